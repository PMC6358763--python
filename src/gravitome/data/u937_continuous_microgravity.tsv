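gene_symbol	entrez_id	probe_set_id	fc_short	fc_long
IL1B	3553	NM_000576	-1.65	-1.43
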