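# Previously published Monte Carlo estimates of the Pro concentration control
# coefficient distribution (median, 10th and 90th percentile) per reaction, for
# the L. perenne (lp) and M. lupulina (ml) parameterizations under ambient climate.
# Used only for side-by-side comparison reports; never fed into computations.
condition	reaction	median	p10	p90
lp	ARG	0.051	0.023	0.11
lp	OAT	0.1	0.054	0.26
lp	GS	-0.056	-0.28	-0.009
lp	GOGAT	-0.017	-0.098	-0.0016
lp	GDH	-0.085	-0.19	-0.032
lp	P5CS	0.056	-0.0035	0.25
lp	P5CDH	-0.016	-0.098	0.00083
lp	P5CR	0.069	0.011	0.25
lp	PRODH	-0.021	-0.097	-0.0032
lp	AKGPR	0.77	0.020	2.4
lp	GLUPR	0.31	-0.18	1.4
lp	PROCO	-0.96	-0.99	-0.87
ml	ARG	0.05	0.023	0.12
ml	OAT	0.11	0.056	0.24
ml	GS	-0.053	-0.29	0.0098
ml	GOGAT	-0.014	-0.086	-0.0013
ml	GDH	-0.079	-0.18	-0.033
ml	P5CS	0.039	-0.013	0.24
ml	P5CDH	-0.012	-0.086	0.0039
ml	P5CR	0.064	0.0059	0.25
ml	PRODH	-0.02	-0.086	-0.0016
ml	AKGPR	0.71	0.095	2.3
ml	GLUPR	0.25	-0.20	1.3
ml	PROCO	-0.97	-1.0	-0.88
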