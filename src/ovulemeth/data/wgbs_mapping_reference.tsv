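sample	raw_reads	clean_reads	mapped_reads	mapping_rate_pct	unique_reads	unique_rate_pct	conversion_rate_pct
Gui99	64633950	55303794	37874308	68.48	31496782	56.95	99.42
fsv1	58193179	49677100	34160912	68.77	28555851	57.48	99.21
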