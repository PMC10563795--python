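gene	class	weight
MOF001	classical	8.00
MOF001	basal	2.63
MOF002	classical	7.53
MOF002	basal	3.10
MOF003	classical	8.43
MOF003	basal	2.65
MOF004	classical	7.63
MOF004	basal	2.57
MOF005	classical	8.12
MOF005	basal	3.45
MOF006	classical	8.01
MOF006	basal	2.87
MOF007	classical	7.78
MOF007	basal	3.16
MOF008	classical	8.29
MOF008	basal	2.64
MOF009	classical	8.01
MOF009	basal	3.17
MOF010	classical	8.05
MOF010	basal	3.32
MOF011	classical	7.70
MOF011	basal	3.48
MOF012	classical	7.98
MOF012	basal	3.05
MOF013	classical	8.09
MOF013	basal	2.85
MOF014	classical	8.30
MOF014	basal	2.74
MOF015	classical	7.63
MOF015	basal	3.37
MOF016	classical	2.97
MOF016	basal	7.78
MOF017	classical	2.58
MOF017	basal	8.40
MOF018	classical	2.93
MOF018	basal	7.65
MOF019	classical	3.17
MOF019	basal	7.70
MOF020	classical	3.40
MOF020	basal	7.72
MOF021	classical	2.53
MOF021	basal	7.70
MOF022	classical	2.85
MOF022	basal	7.97
MOF023	classical	3.41
MOF023	basal	8.20
MOF024	classical	2.84
MOF024	basal	7.52
MOF025	classical	2.66
MOF025	basal	8.50
MOF026	classical	2.96
MOF026	basal	8.19
MOF027	classical	2.55
MOF027	basal	7.53
MOF028	classical	3.35
MOF028	basal	8.09
MOF029	classical	2.81
MOF029	basal	7.82
MOF030	classical	2.59
MOF030	basal	7.67
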