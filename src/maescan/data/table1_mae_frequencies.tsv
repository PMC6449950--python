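# Published per-cell-line MAE frequencies (15 melanoma lines vs parental TILs)
cell_line	mutational_status	mae_frequency	mae_frequency_imputed
Mel2805	WT	0.26	0.36
Mel1866	NRAS	0.72	0.77
Mel2075	NRAS	0.77	0.80
Mel2155	NRAS	0.73	0.76
Mel2427	NRAS	0.56	0.65
Mel2744	NRAS	0.39	0.47
Mel3107	NRAS	0.35	0.43
Mel2035	BRAF	0.75	0.79
Mel2224	BRAF	0.76	0.80
Mel2448	BRAF	0.74	0.77
Mel2458	BRAF	0.18	0.28
Mel2492	BRAF	0.68	0.73
Mel2523	BRAF	0.29	0.36
Mel3025	BRAF	0.74	0.79
Mel3104	BRAF	0.17	0.28
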