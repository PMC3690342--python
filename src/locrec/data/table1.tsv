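compartment	n_fp	n_confirmed	n_contradicted	printed_pct_agree	printed_pct_disagree	n_unvalidated
cytoskeleton	63	0	24	0	100	39
cytosol	514	119	101	54	46	294
endoplasmic_reticulum	189	31	56	36	64	102
extracellular	40	9	10	47	53	21
golgi	145	42	57	42	58	46
mitochondrion	312	90	54	63	37	168
nucleus	779	95	149	39	61	535
peroxisome	130	59	33	64	36	38
plasma_membrane	245	122	17	88	12	106
plastid	486	248	34	88	12	203
vacuole	93	34	18	65	34	41
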