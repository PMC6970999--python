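# Hand-verified inheritance-mode truth table: all 12 chrX trio genotype
# combinations for a male proband (haploid proband and father {0, 1},
# diploid mother {0/0, 0/1, 1/1}).
# X_LINKED: proband carries alt, mother carries alt, father does not.
# DE_NOVO: proband carries alt, neither parent does.
# modes column: '+'-joined mode names, '-' for none.
proband	mother	father	modes
0	0/0	0	-
0	0/0	1	-
0	0/1	0	-
0	0/1	1	-
0	1/1	0	-
0	1/1	1	-
1	0/0	0	DE_NOVO
1	0/0	1	-
1	0/1	0	X_LINKED
1	0/1	1	-
1	1/1	0	X_LINKED
1	1/1	1	-
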