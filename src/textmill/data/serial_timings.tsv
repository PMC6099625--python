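# Published serial benchmark: total time to run three NER plugins over
# inputs of different total sizes, single process.
# columns: size_mb	total_seconds
1	1812.53
2	3083.69
4	5680.40
8	9742.16
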