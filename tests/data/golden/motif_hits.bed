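chr2	36667	36679	FoxA1	1000	+
chr2	69903	69915	FoxA1	1000	-
chr2	77998	78010	FoxA1	1000	+
chr2	80813	80825	FoxA1	1000	-
chr2	85531	85543	FoxA1	1000	+
chr2	86295	86307	FoxA1	1000	-
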