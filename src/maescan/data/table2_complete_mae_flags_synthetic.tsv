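# Complete-chromosome MAE flags per cell line, SYNTHETIC reconstruction.
# Row totals (flags per sample), column totals (flags per chromosome, chr9 = 11)
# and Mel2744's flagged chromosomes {1, 9, 17, 18} are published values; the
# remaining cell assignments are one feasible 0/1 matrix consistent with those
# margins, constructed here because the per-cell assignments were not machine-
# readable from the source.
cell_line	mutational_status	flagged_chromosomes
Mel2224	BRAF	2,4,9,10,12
Mel2744	NRAS	1,9,17,18
Mel2035	BRAF	2,9,10,12
Mel2458	BRAF	8,10
Mel2492	BRAF	
Mel1866	NRAS	8,9,14
Mel2075	NRAS	4,9,10,11,14
Mel2523	BRAF	9,10,11,14
Mel2805	WT	9,13,22
Mel2427	NRAS	
Mel3107	NRAS	9,13,22
Mel2448	BRAF	3,4,9,10,12,22
Mel3025	BRAF	1,5,9,10
Mel3104	BRAF	17
Mel2155	NRAS	1,9,18
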