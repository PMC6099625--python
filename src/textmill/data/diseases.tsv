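# fixture disease lexicon: surface form <TAB> MeSH id
melanoma	D008545
breast cancer	D001943
cancer	D009369
thyroid cancer	D013964
lung cancer	D008175
colorectal cancer	D015179
leukemia	D007938
lymphoma	D008223
glioblastoma	D005909
neurofibromatosis	D009456
diabetes	D003920
hypertension	D006973
asthma	D001249
epilepsy	D004827
anemia	D000740
melanocytic nevus	D009506
ovarian cancer	D010051
prostate cancer	D011471
pancreatic cancer	D010190
gastric cancer	D013274
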