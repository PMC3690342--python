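compartment	cytoskeleton	cytosol	endoplasmic_reticulum	extracellular	golgi	mitochondrion	nucleus	peroxisome	plasma_membrane	plastid	vacuole
cytoskeleton	63
cytosol	11	514
endoplasmic_reticulum	3	15	189
extracellular	1	3	1	40
golgi	3	21	28	2	145
mitochondrion	2	12	4	0	2	312
nucleus	12	238	13	4	1	8	779
peroxisome	2	11	2	0	1	10	5	130
plasma_membrane	8	45	21	14	22	3	23	0	145
plastid	2	16	10	0	2	100	7	8	3	486
vacuole	1	5	10	1	10	0	2	2	7	2	93
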