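mir_id	ESR1	FOS	FoxA1	FoxA2	IRF4	JunD	RELA	Stat3
let-7a-5p	4	9	8	6	3	3	6	6
let-7f-5p	3	4	5	6	4	5	4	1
miR-150-5p	6	23	14	12	13	13	6	11
miR-151a-3p	8	10	4	6	5	9	3	6
miR-21-5p	13	6	5	13	12	15	4	23
miR-30e-5p	10	10	17	14	13	14	12	16
miR-423-5p	17	16	5	18	11	13	16	12
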