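# Sequence Ontology consequence terms mapped to impact classes, ordered by
# severity (rank 1 = most severe), following the common annotator convention.
# version: 1.0
# columns: term	impact	rank
transcript_ablation	HIGH	1
splice_acceptor_variant	HIGH	2
splice_donor_variant	HIGH	3
stop_gained	HIGH	4
frameshift_variant	HIGH	5
stop_lost	HIGH	6
start_lost	HIGH	7
transcript_amplification	HIGH	8
feature_elongation	HIGH	9
feature_truncation	HIGH	10
inframe_insertion	MODERATE	11
inframe_deletion	MODERATE	12
missense_variant	MODERATE	13
protein_altering_variant	MODERATE	14
splice_donor_5th_base_variant	LOW	15
splice_region_variant	LOW	16
splice_donor_region_variant	LOW	17
splice_polypyrimidine_tract_variant	LOW	18
incomplete_terminal_codon_variant	LOW	19
start_retained_variant	LOW	20
stop_retained_variant	LOW	21
synonymous_variant	LOW	22
coding_sequence_variant	MODIFIER	23
mature_miRNA_variant	MODIFIER	24
5_prime_UTR_variant	MODIFIER	25
3_prime_UTR_variant	MODIFIER	26
non_coding_transcript_exon_variant	MODIFIER	27
intron_variant	MODIFIER	28
NMD_transcript_variant	MODIFIER	29
non_coding_transcript_variant	MODIFIER	30
coding_transcript_variant	MODIFIER	31
upstream_gene_variant	MODIFIER	32
downstream_gene_variant	MODIFIER	33
TFBS_ablation	MODIFIER	34
TFBS_amplification	MODIFIER	35
TF_binding_site_variant	MODIFIER	36
regulatory_region_ablation	MODIFIER	37
regulatory_region_amplification	MODIFIER	38
regulatory_region_variant	MODIFIER	39
intergenic_variant	MODIFIER	40
sequence_variant	MODIFIER	41
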