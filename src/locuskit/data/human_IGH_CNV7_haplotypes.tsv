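# species: Homo sapiens
# locus: IGH
# Haplotypes A-G of the heavy-chain constant CNV (orders 203-211).  Haplotype
# A is the most frequent configuration with all nine genes; haplotypes B-G
# correspond to the multigene deletions I-VI found on both chromosomes 14 in
# healthy individuals, encoded as contiguous absent blocks.  Haplotype D
# (deletion III) spans IGHA1..IGHE inclusive of IGHGP, matching the individual
# lacking IgA1, IgG2, IgG4 and IgE; the remaining blocks are schematic
# contiguous encodings consistent with the missing-isotype reports and are
# exercised by invariant tests only.
gene_name	functionality	order	orientation	cnv_role	A	B	C	D	E	F	G
IGHG3	F	203	direct	CNV7	present	present	present	present	absent	present	present
IGHG1	F	204	direct	CNV7	present	absent	present	present	absent	present	present
IGHEP1	P	205	direct	CNV7	present	absent	present	present	present	present	present
IGHA1	F	206	direct	CNV7	present	absent	absent	absent	present	present	present
IGHGP	ORF, P	207	direct	CNV7	present	absent	absent	absent	present	present	present
IGHG2	F	208	direct	CNV7	present	absent	absent	absent	present	absent	present
IGHG4	F	209	direct	CNV7	present	absent	absent	absent	present	absent	absent
IGHE	F	210	direct	CNV7	present	present	present	absent	present	absent	absent
IGHA2	F	211	direct	CNV7	present	present	present	present	present	present	absent
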