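# fixture gene lexicon: surface form <TAB> NCBI gene id
BRAF	673
TP53	7157
EGFR	1956
KRAS	3845
BRCA1	672
BRCA2	675
PTEN	5728
PIK3CA	5290
ALK	238
RET	5979
MET	4233
KIT	3815
NRAS	4893
JAK2	3717
ABL1	25
MYC	4609
ERBB2	2064
CDKN2A	1029
VHL	7428
APC	324
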