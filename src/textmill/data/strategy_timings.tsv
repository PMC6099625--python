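# Published multi-node NER benchmark: per-strategy maximum (MET) and average
# (AET) execution times in seconds, by number of parallel processes, on a
# 16 MB / 175-article corpus processed by three NER plugins.
# columns: n_procs	strategy	max_seconds	mean_seconds
2	random	8676.60	8513.10
2	round_robin	8651.42	8374.08
2	short_board	8466.89	8392.46
4	random	4466.81	4001.38
4	round_robin	5211.96	4535.42
4	short_board	4596.09	4393.07
8	random	2792.29	2287.19
8	round_robin	2706.41	2354.14
8	short_board	2386.45	2242.42
16	random	1737.94	1265.46
16	round_robin	1457.01	1174.12
16	short_board	1475.07	1270.33
32	random	932.85	624.73
32	round_robin	942.10	666.91
32	short_board	930.25	640.63
64	random	609.06	379.08
64	round_robin	579.8	376.06
64	short_board	553.42	366.84
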