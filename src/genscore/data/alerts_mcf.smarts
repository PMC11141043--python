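# Curated medicinal-chemistry structural alerts (reactive, unstable or
# promiscuous groups), one SMARTS per line with a tab-separated name.
# Written for this package; used together with the toolkit's PAINS catalog
# by the `filters` evaluation metric.
[CX3](=O)[Cl,Br,I]	acyl_halide
[CX3H1](=O)[#6]	aldehyde
C1OC1	epoxide
C1NC1	aziridine
N=C=O	isocyanate
N=C=S	isothiocyanate
[SX2H]	thiol
[CX3]=[CX3][CX3]=[OX1]	michael_acceptor
[CX4;!$(C(F)(F)F)][Cl,Br,I]	alkyl_halide
N=[N+]=[N-]	azide
[NX2]=[NX2]	azo
[OX2][OX2]	peroxide
[NX3][NX3H2]	hydrazine
[SX2][SX2]	disulfide
C(=O)OC(=O)	anhydride
S(=O)(=O)[Cl,Br]	sulfonyl_halide
[P;!$(P(=O)([O,N])([O,N])[O,N])]	phosphorus_nonphosphate
[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I].[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]	polyhalide
[N+](=O)[O-][CX4]	aliphatic_nitro
C=[N+]=[N-]	diazo
[CH2X4][CH2X4][CH2X4][CH2X4][CH2X4][CH2X4][CH2X4]	long_aliphatic_chain
[OX1]=[CX3]([F,Cl,Br,I])	haloketone
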