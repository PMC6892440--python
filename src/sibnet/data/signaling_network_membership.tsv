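gene	patients	PI3K-AKT-mTOR	NGF-PC12	AVB3-INTEGRIN	PI3K-ERBB2/4	SEMA3A-PKA	REELIN
AKAP9	3	0	0	0	0	0	0
AKT1	3	1	1	1	1	0	1
AKT2	3	1	1	1	1	0	0
ARHGEF2	3	0	1	0	0	0	1
BCR	4	0	0	0	0	0	0
CYTH3	19	1	0	0	0	0	0
GNA12	3	0	0	0	0	0	0
HSP90AA1	3	1	1	1	0	1	0
IRS1	17	1	1	1	1	0	0
LRP1	5	0	0	0	0	0	0
MAPK8IP1	10	0	1	1	0	0	1
MAPK8IP3	3	0	1	1	0	0	0
PFKL	4	0	0	0	0	0	0
PKN1	4	0	0	0	0	0	0
PLXNA1	13	0	0	0	0	1	0
PLXNA2	8	0	0	0	0	1	0
TSC2	4	1	1	0	1	0	0
TUBB4B	4	0	0	0	0	0	0
VEGFA	9	1	0	1	0	0	0
YWHAE	4	1	1	0	0	0	0
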