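tf	per_region_sum	dedup_total
FOS	176	78
FoxA2	168	75
Stat3	162	75
JunD	155	72
ESR1	129	61
IRF4	139	61
FoxA1	122	58
RELA	119	51
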