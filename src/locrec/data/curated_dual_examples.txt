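# Example curated list of known dual-targeted or dynamic Arabidopsis
# proteins, one AGI locus per line. This file is documentation of the
# input format, not an authority: triage treats whatever list the user
# supplies as the curated set.
# dynamin 3A — mitochondrion/peroxisome dual-targeted
AT4G33650
# lon1 protease — mitochondrion/plastid dual-targeted
AT5G26860
# alanyl-tRNA synthetase — cytosol/mitochondrion/plastid via alternative start codons
AT1G50200
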