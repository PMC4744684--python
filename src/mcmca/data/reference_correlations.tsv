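# Previously published Pearson correlation coefficients between per-run Pro
# control coefficients of reaction pairs, for the L. perenne (lp) and
# M. lupulina (ml) parameterizations under ambient climate.
condition	reaction_a	reaction_b	cc
lp	ARG	OAT	0.64
ml	ARG	OAT	0.63
lp	P5CS	P5CR	0.60
ml	P5CS	P5CR	0.49
lp	GS	P5CS	-0.66
ml	GS	P5CS	-0.64
lp	P5CS	P5CDH	-0.79
ml	P5CS	P5CDH	-0.76
lp	P5CR	PRODH	-0.69
ml	P5CR	PRODH	-0.76
lp	PRODH	PROCO	-0.81
ml	PRODH	PROCO	-0.80
lp	P5CR	PROCO	-0.63
ml	P5CR	PROCO	-0.52
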