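gene_symbol	entrez_id	probe_set_id	fc_short	fc_long
SLC2A1	6513	TC01002578.hg.1	-1.11	-1.03
PIK3R3; RP11-322N21.2	8503	TC01002616.hg.1	1.05	1.3
ARNT	405	TC01003212.hg.1	1.15	1.1
PDK1	5163	TC02001031.hg.1	1.07	1.17
VHL	7428	TC03000055.hg.1	1.07	1.17
PIK3CA	5290	TC03000951.hg.1	1.18	1.63
CAMK2D	817	TC04001486.hg.1	1.11	1.06
MAPK14	1432	TC06000523.hg.1	1.08	1.14
IFNGR1	3459	TC06002152.hg.1	1.13	1.36
NOS3; ATG9B	4846	TC07001009.hg.1	-1.03	-1.12
RPS6	6194	TC09000938.hg.1	1.13	1.32
VIM	7431	TC10000126.hg.1	1.19	1.14
CDKN1B	1027	TC12000178.hg.1	1.38	1.06
FLT1	2321	TC13000517.hg.1	1.12	1.32
HIF1A	3091	TC14002197.hg.1	1.25	1.66
MAP2K1	5604	TC15000613.hg.1	1.3	1.07
IGF1R	3480	TC15000949.hg.1	1.18	1.08
PRKCB	5579	TC16000260.hg.1	1.06	1.12
STAT3	6774	TC17001531.hg.1	1.33	1.26
AKT2	208	TC19001532.hg.1	-1.08	-1.09
PFKL	5211	TC21000222.hg.1	-1.13	-1.07
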