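# Reaction free energies (kJ/mol) for the L. perenne parameterization, ambient climate.
# dG0_prime: biochemical standard reaction free energy; dG_prime: adjusted for measured
# metabolite concentrations. Reactions are oriented along expected net flux (GDH toward
# Glu production, P5CR toward Pro production). Boundary steps carry no thermodynamics.
reaction_id	dG0_prime_kJ_mol	dG_prime_kJ_mol
ARG	66.2	43
OAT	-26.9	-20
GDH	-38.1	-11
GOGAT	-51.4	-44
GS	-22.8	-28
P5CS	-8.33	-29
P5CR	-31.1	-29
PRODH	31	25
P5CDH	-27.8	-32
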