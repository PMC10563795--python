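chrom	start	end	gene
1	20000000	20140000	ATM
1	30000000	30041000	CTNNB1
1	40000000	40086000	ARID1A
1	45000000	45023000	STK11
1	60000000	60047000	PARP1
1	75000000	75030000	RIT1
1	90000000	90130000	ATR
1	100000000	100044000	SF3B1
1	110000000	110081000	BRCA1
2	10000000	10045000	KRAS
2	30000000	30027000	CDKN2A
2	40000000	40123000	MAP2K4
2	50000000	50019000	IDH1
2	70000000	70037000	RAD51
2	90000000	90050000	CHEK2
2	100000000	100190000	BRAF
2	105000000	105190000	EGFR
3	10000000	10130000	RBM10
3	20000000	20030000	XRCC2
3	25000000	25049000	TGFBR1
3	30000000	30240000	KDM6A
3	35000000	35105000	PTEN
3	60000000	60108000	APC
3	70000000	70071000	GNAS
3	80000000	80030000	MDM2
3	88000000	88140000	ROS1
3	95000000	95090000	PIK3CA
4	5000000	5020000	TP53
4	15000000	15088000	TGFBR2
4	25000000	25084000	BRCA2
4	40000000	40050000	SMAD4
4	50000000	50038000	PALB2
4	60000000	60060000	RNF43
4	65000000	65126000	MET
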