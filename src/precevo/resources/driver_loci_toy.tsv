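gene	chrom	pos	label
KRAS	2	10005000	G12D
TP53	4	5005000	R175H
SMAD4	4	40005000	R361C
CDKN2A	2	30005000	R80X
GNAS	3	70005000	R201C
BRAF	2	100005000	V600E
PIK3CA	3	95005000	E545K
MAP2K4	2	40005000	R154W
TGFBR1	3	25005000	R487Q
TGFBR2	4	15005000	R537C
RNF43	4	60005000	G659fs
CTNNB1	1	30005000	S37F
STK11	1	45005000	F354L
ARID1A	1	40005000	R1989X
KDM6A	3	30005000	Q555X
SF3B1	1	100005000	K700E
RBM10	3	10005000	Q595X
IDH1	2	50005000	R132H
PTEN	3	35005000	R130G
APC	3	60005000	R1450X
ATM	1	20005000	R337C
BRCA1	1	110005000	Q1756fs
BRCA2	4	25005000	K3326X
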