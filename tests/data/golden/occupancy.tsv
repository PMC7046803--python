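mir_id	region_type	ESR1	FOS	FoxA1	FoxA2	IRF4	JunD	RELA	Stat3
let-7a-5p	mir_enhancer	4	9	8	6	3	3	6	6
let-7a-5p	mir_promoter	1	5	3	2	2	1	6	5
let-7f-5p	mir_enhancer	3	4	5	6	4	5	4	1
let-7f-5p	mir_promoter	2	2	1	3	2	2	3	0
miR-150-5p	host_enhancer	6	23	14	12	13	13	6	11
miR-150-5p	host_promoter	2	8	2	1	1	5	1	1
miR-150-5p	mir_enhancer	6	23	12	11	12	11	6	8
miR-150-5p	mir_promoter	3	6	5	5	6	0	3	0
miR-151a-3p	mir_enhancer	8	10	4	6	5	9	3	6
miR-151a-3p	mir_promoter	5	4	3	6	3	5	0	3
miR-21-5p	host_enhancer	13	6	5	13	12	15	4	23
miR-21-5p	host_promoter	1	1	1	2	5	6	0	5
miR-21-5p	mir_enhancer	10	6	4	12	12	14	2	18
miR-21-5p	mir_promoter	3	2	1	3	1	3	1	7
miR-30e-5p	host_enhancer	10	10	17	14	13	14	12	16
miR-30e-5p	host_promoter	3	5	7	3	4	5	4	4
miR-30e-5p	mir_enhancer	10	10	13	13	12	12	11	12
miR-30e-5p	mir_promoter	3	2	3	5	3	3	5	5
miR-423-5p	host_enhancer	17	16	5	18	11	13	16	12
miR-423-5p	host_promoter	6	3	2	5	3	2	6	2
miR-423-5p	mir_enhancer	13	15	5	18	10	11	14	12
miR-423-5p	mir_promoter	0	6	2	4	2	3	6	5
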