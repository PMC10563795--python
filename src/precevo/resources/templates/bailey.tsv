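gene	class	weight
BAI001	progenitor	8.07
BAI001	squamous	2.94
BAI001	adex	2.94
BAI001	immunogenic	2.94
BAI002	progenitor	7.75
BAI002	squamous	3.41
BAI002	adex	3.41
BAI002	immunogenic	3.41
BAI003	progenitor	7.86
BAI003	squamous	3.09
BAI003	adex	3.09
BAI003	immunogenic	3.09
BAI004	progenitor	8.04
BAI004	squamous	3.26
BAI004	adex	3.26
BAI004	immunogenic	3.26
BAI005	progenitor	8.02
BAI005	squamous	2.70
BAI005	adex	2.70
BAI005	immunogenic	2.70
BAI006	progenitor	7.55
BAI006	squamous	2.74
BAI006	adex	2.74
BAI006	immunogenic	2.74
BAI007	progenitor	7.84
BAI007	squamous	2.61
BAI007	adex	2.61
BAI007	immunogenic	2.61
BAI008	progenitor	8.27
BAI008	squamous	2.52
BAI008	adex	2.52
BAI008	immunogenic	2.52
BAI009	progenitor	7.52
BAI009	squamous	3.30
BAI009	adex	3.30
BAI009	immunogenic	3.30
BAI010	progenitor	7.93
BAI010	squamous	3.03
BAI010	adex	3.03
BAI010	immunogenic	3.03
BAI011	progenitor	2.90
BAI011	squamous	7.57
BAI011	adex	2.90
BAI011	immunogenic	2.90
BAI012	progenitor	3.44
BAI012	squamous	7.80
BAI012	adex	3.44
BAI012	immunogenic	3.44
BAI013	progenitor	3.43
BAI013	squamous	7.90
BAI013	adex	3.43
BAI013	immunogenic	3.43
BAI014	progenitor	2.71
BAI014	squamous	7.75
BAI014	adex	2.71
BAI014	immunogenic	2.71
BAI015	progenitor	2.75
BAI015	squamous	8.30
BAI015	adex	2.75
BAI015	immunogenic	2.75
BAI016	progenitor	3.33
BAI016	squamous	8.31
BAI016	adex	3.33
BAI016	immunogenic	3.33
BAI017	progenitor	2.77
BAI017	squamous	7.80
BAI017	adex	2.77
BAI017	immunogenic	2.77
BAI018	progenitor	3.04
BAI018	squamous	8.21
BAI018	adex	3.04
BAI018	immunogenic	3.04
BAI019	progenitor	3.21
BAI019	squamous	8.34
BAI019	adex	3.21
BAI019	immunogenic	3.21
BAI020	progenitor	3.26
BAI020	squamous	8.01
BAI020	adex	3.26
BAI020	immunogenic	3.26
BAI021	progenitor	3.19
BAI021	squamous	3.19
BAI021	adex	8.26
BAI021	immunogenic	3.19
BAI022	progenitor	2.69
BAI022	squamous	2.69
BAI022	adex	8.48
BAI022	immunogenic	2.69
BAI023	progenitor	3.04
BAI023	squamous	3.04
BAI023	adex	8.14
BAI023	immunogenic	3.04
BAI024	progenitor	3.17
BAI024	squamous	3.17
BAI024	adex	8.21
BAI024	immunogenic	3.17
BAI025	progenitor	2.59
BAI025	squamous	2.59
BAI025	adex	7.58
BAI025	immunogenic	2.59
BAI026	progenitor	2.80
BAI026	squamous	2.80
BAI026	adex	7.63
BAI026	immunogenic	2.80
BAI027	progenitor	3.25
BAI027	squamous	3.25
BAI027	adex	7.97
BAI027	immunogenic	3.25
BAI028	progenitor	2.68
BAI028	squamous	2.68
BAI028	adex	7.90
BAI028	immunogenic	2.68
BAI029	progenitor	2.70
BAI029	squamous	2.70
BAI029	adex	8.25
BAI029	immunogenic	2.70
BAI030	progenitor	2.90
BAI030	squamous	2.90
BAI030	adex	8.35
BAI030	immunogenic	2.90
BAI031	progenitor	3.21
BAI031	squamous	3.21
BAI031	adex	3.21
BAI031	immunogenic	7.96
BAI032	progenitor	3.07
BAI032	squamous	3.07
BAI032	adex	3.07
BAI032	immunogenic	8.50
BAI033	progenitor	3.22
BAI033	squamous	3.22
BAI033	adex	3.22
BAI033	immunogenic	7.93
BAI034	progenitor	2.89
BAI034	squamous	2.89
BAI034	adex	2.89
BAI034	immunogenic	8.35
BAI035	progenitor	3.13
BAI035	squamous	3.13
BAI035	adex	3.13
BAI035	immunogenic	8.19
BAI036	progenitor	2.66
BAI036	squamous	2.66
BAI036	adex	2.66
BAI036	immunogenic	7.94
BAI037	progenitor	2.52
BAI037	squamous	2.52
BAI037	adex	2.52
BAI037	immunogenic	8.04
BAI038	progenitor	2.52
BAI038	squamous	2.52
BAI038	adex	2.52
BAI038	immunogenic	8.15
BAI039	progenitor	2.65
BAI039	squamous	2.65
BAI039	adex	2.65
BAI039	immunogenic	7.57
BAI040	progenitor	2.66
BAI040	squamous	2.66
BAI040	adex	2.66
BAI040	immunogenic	7.92
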