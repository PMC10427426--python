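gene	is_oncogene
ERBB2	1
PIK3CA	1
MYC	1
CCND1	1
EGFR	1
FGFR1	1
ESR1	1
GATA3	1
AKT1	1
KRAS	1
SLX4	0
TP53	0
PTEN	0
RB1	0
BRCA1	0
BRCA2	0
NF1	0
ARID1A	0
CDH1	0
MAP3K1	0
NFKBIA	0
CDKN2A	0
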