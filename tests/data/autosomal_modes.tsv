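# Hand-verified inheritance-mode truth table: all 27 autosomal diploid trio
# genotype combinations (proband, mother, father over {0/0, 0/1, 1/1}).
# DE_NOVO: proband carries alt, both parents 0/0.
# AUTOSOMAL_RECESSIVE (strict model): proband 1/1, both parents 0/1.
# modes column: '+'-joined mode names, '-' for none.
proband	mother	father	modes
0/0	0/0	0/0	-
0/0	0/0	0/1	-
0/0	0/0	1/1	-
0/0	0/1	0/0	-
0/0	0/1	0/1	-
0/0	0/1	1/1	-
0/0	1/1	0/0	-
0/0	1/1	0/1	-
0/0	1/1	1/1	-
0/1	0/0	0/0	DE_NOVO
0/1	0/0	0/1	-
0/1	0/0	1/1	-
0/1	0/1	0/0	-
0/1	0/1	0/1	-
0/1	0/1	1/1	-
0/1	1/1	0/0	-
0/1	1/1	0/1	-
0/1	1/1	1/1	-
1/1	0/0	0/0	DE_NOVO
1/1	0/0	0/1	-
1/1	0/0	1/1	-
1/1	0/1	0/0	-
1/1	0/1	0/1	AUTOSOMAL_RECESSIVE
1/1	0/1	1/1	-
1/1	1/1	0/0	-
1/1	1/1	0/1	-
1/1	1/1	1/1	-
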