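mir_id	region_type	chrom	start	end	H3K4me3	H3K4me1	H3K27ac	call
let-7a-5p	mir_enhancer	chr2	154183	174277	1	1	1	active_promoter
let-7a-5p	mir_promoter	chr2	164277	166277	1	0	1	active_promoter
let-7f-5p	mir_enhancer	chr1	126744	146840	1	1	1	active_promoter
let-7f-5p	mir_promoter	chr1	136840	138840	1	0	1	active_promoter
miR-150-5p	host_enhancer	chr2	18941	51433	1	1	1	active_promoter
miR-150-5p	host_promoter	chr2	26941	28941	1	1	1	active_promoter
miR-150-5p	mir_enhancer	chr2	26294	46383	1	1	1	active_promoter
miR-150-5p	mir_promoter	chr2	36383	38383	1	0	0	active_promoter
miR-151a-3p	mir_enhancer	chr1	157692	177802	1	1	1	active_promoter
miR-151a-3p	mir_promoter	chr1	167802	169802	1	0	1	active_promoter
miR-21-5p	host_enhancer	chr2	62901	94211	1	1	1	active_promoter
miR-21-5p	host_promoter	chr2	84211	86211	1	0	1	active_promoter
miR-21-5p	mir_enhancer	chr2	71218	91307	1	1	1	active_promoter
miR-21-5p	mir_promoter	chr2	79218	81218	1	0	1	active_promoter
miR-30e-5p	host_enhancer	chr1	85206	115476	1	1	1	active_promoter
miR-30e-5p	host_promoter	chr1	105476	107476	1	0	1	active_promoter
miR-30e-5p	mir_enhancer	chr1	87959	108066	1	1	1	active_promoter
miR-30e-5p	mir_promoter	chr1	95959	97959	1	1	0	active_promoter
miR-423-5p	host_enhancer	chr1	50186	79641	1	1	1	active_promoter
miR-423-5p	host_promoter	chr1	69641	71641	1	0	1	active_promoter
miR-423-5p	mir_enhancer	chr1	56069	76174	1	1	1	active_promoter
miR-423-5p	mir_promoter	chr1	66174	68174	1	1	0	active_promoter
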