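family	AChR+	MuSK+	unassigned
AP1	81	69	0
EGR	0	0	0
ESR	29	32	0
FOXO_group	75	58	0
IRF	38	23	0
NFAT	0	0	0
NFKB	22	29	0
STAT	50	25	0
unassigned	0	0	0
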