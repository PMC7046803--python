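family	AChR+	MuSK+	unassigned
AP1	203	128	0
EGR	0	0	0
ESR	70	59	0
FOXO_group	178	112	0
IRF	94	45	0
NFAT	0	0	0
NFKB	55	64	0
STAT	110	52	0
unassigned	0	0	0
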