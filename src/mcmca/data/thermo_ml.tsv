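# Reaction free energies (kJ/mol) for the M. lupulina parameterization, ambient climate.
# Same conventions as thermo_lp.tsv.
reaction_id	dG0_prime_kJ_mol	dG_prime_kJ_mol
ARG	66.2	36
OAT	-26.9	-20
GDH	-38.1	-7
GOGAT	-51.4	-36
GS	-22.8	-32
P5CS	-8.33	-36
P5CR	-31.1	-24
PRODH	31	20
P5CDH	-27.8	-25
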