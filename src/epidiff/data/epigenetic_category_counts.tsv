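category	gene_function	n_transcripts	CAT1	CAT2	CAT3
a	DNA methyltransferases (DNMT)	3	2	33	6
b	Methyl-binding domain proteins (MBD)	6	2	43	8
c	Histone acetyltransferases (HAT)	11	8	164	13
d	Histone deacetylases (HDAC)	8	2	318	9
e	Histone methyltransferases (HMT)	32	26	637	37
f	Histone demethylase	1	0	12	2
g	Histones	30	3	18	43
h	Polycomb-group proteins	3	0	14	6
i	Chromatin-remodeling factors	99	70	1499	116
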