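gene_symbol	entrez_id	probe_set_id	fc_short	fc_long
SERPINE1	5054	NM_000602	2.16	1.50
PDK1	5163	BC039158	1.30	1.48
PDK1	5163	NM_002610	1.23	1.62
SLC2A3	6515	NM_006931	1.81	1.50
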