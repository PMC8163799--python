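# Sugimoto et al. (1995) RNA:DNA hybrid parameters (RNA strand written in DNA alphabet).
# Nearest-neighbor thermodynamic parameters.
# dimer = top (protospacer/RNA-transcript) strand 5'->3'; dH kcal/mol, dS cal/(mol K).
# Conditions: 1 M NaCl, 37 C reference for dG37 = dH - 310.15*dS/1000.
dimer	dH	dS
AA	-7.8	-21.9
AC	-5.9	-12.3
AG	-9.1	-23.5
AT	-8.3	-23.9
CA	-9.0	-26.1
CC	-9.3	-23.2
CG	-16.3	-47.1
CT	-7.0	-19.7
GA	-5.5	-13.5
GC	-8.0	-17.1
GG	-12.8	-31.9
GT	-7.8	-21.6
TA	-7.8	-23.2
TC	-8.6	-22.9
TG	-10.4	-28.4
TT	-11.5	-36.4
init	1.9	-3.9
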