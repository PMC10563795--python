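gene	class	weight
COL001	classical	7.70
COL001	qm	2.87
COL001	exocrine	2.87
COL002	classical	8.15
COL002	qm	2.59
COL002	exocrine	2.59
COL003	classical	8.49
COL003	qm	2.96
COL003	exocrine	2.96
COL004	classical	8.34
COL004	qm	3.35
COL004	exocrine	3.35
COL005	classical	8.06
COL005	qm	2.55
COL005	exocrine	2.55
COL006	classical	7.55
COL006	qm	3.11
COL006	exocrine	3.11
COL007	classical	7.83
COL007	qm	2.98
COL007	exocrine	2.98
COL008	classical	8.30
COL008	qm	2.72
COL008	exocrine	2.72
COL009	classical	7.60
COL009	qm	2.92
COL009	exocrine	2.92
COL010	classical	8.41
COL010	qm	2.87
COL010	exocrine	2.87
COL011	classical	7.69
COL011	qm	2.89
COL011	exocrine	2.89
COL012	classical	8.01
COL012	qm	2.57
COL012	exocrine	2.57
COL013	classical	3.17
COL013	qm	7.91
COL013	exocrine	3.17
COL014	classical	3.35
COL014	qm	8.02
COL014	exocrine	3.35
COL015	classical	3.30
COL015	qm	8.07
COL015	exocrine	3.30
COL016	classical	3.09
COL016	qm	7.91
COL016	exocrine	3.09
COL017	classical	2.61
COL017	qm	8.20
COL017	exocrine	2.61
COL018	classical	3.36
COL018	qm	8.23
COL018	exocrine	3.36
COL019	classical	2.92
COL019	qm	7.59
COL019	exocrine	2.92
COL020	classical	2.69
COL020	qm	8.05
COL020	exocrine	2.69
COL021	classical	3.16
COL021	qm	7.53
COL021	exocrine	3.16
COL022	classical	3.44
COL022	qm	8.21
COL022	exocrine	3.44
COL023	classical	3.22
COL023	qm	8.49
COL023	exocrine	3.22
COL024	classical	3.12
COL024	qm	7.99
COL024	exocrine	3.12
COL025	classical	2.72
COL025	qm	2.72
COL025	exocrine	8.19
COL026	classical	3.20
COL026	qm	3.20
COL026	exocrine	8.45
COL027	classical	3.43
COL027	qm	3.43
COL027	exocrine	7.99
COL028	classical	3.35
COL028	qm	3.35
COL028	exocrine	8.46
COL029	classical	2.92
COL029	qm	2.92
COL029	exocrine	8.11
COL030	classical	3.09
COL030	qm	3.09
COL030	exocrine	7.98
COL031	classical	2.97
COL031	qm	2.97
COL031	exocrine	7.72
COL032	classical	2.69
COL032	qm	2.69
COL032	exocrine	7.81
COL033	classical	3.09
COL033	qm	3.09
COL033	exocrine	8.16
COL034	classical	3.32
COL034	qm	3.32
COL034	exocrine	7.79
COL035	classical	3.02
COL035	qm	3.02
COL035	exocrine	7.95
COL036	classical	2.67
COL036	qm	2.67
COL036	exocrine	8.48
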