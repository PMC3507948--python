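# Seven residues reported as type-II diverged between the vertebrate RPE65
# and BCMO2 clades (divergence value > 3), numbered on the RPE65 reference.
# position	residue
49	L
64	Q
92	A
332	K
415	A
437	L
451	N
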