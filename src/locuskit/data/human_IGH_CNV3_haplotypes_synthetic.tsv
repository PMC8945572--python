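# species: Homo sapiens
# locus: IGH
# SYNTHETIC stand-in encoding of the six haplotypes A-F of the heavy-chain V
# CNV between IGHV4-34 (order 86) and IGHV4-28 (order 113).  Haplotype A is
# the reference main line (all 26 genes of orders 87-112 present); the region
# varies by amplification of a three-to-four-gene motif and the published
# description of haplotypes B-F is graphical only, so their per-gene content
# below is a schematic encoding as contiguous deletion blocks (haplotype F
# lacking the 5'-most amplification unit, the one included by placing the
# 5prime delimiter at IGHV4-34).  Used for structural invariant tests only.
gene_name	functionality	order	orientation	cnv_role	A	B	C	D	E	F
IGHV3-33-2	P	87	direct	CNV3	present	present	present	present	present	absent
IGHV(II)-33-1	P	88	direct	CNV3	present	present	present	present	present	absent
IGHV3-33	F	89	direct	CNV3	present	present	present	present	present	absent
GOLGA4P1	nr	90	direct	CNV3	present	present	present	present	present	absent
IGHV3-32	P	91	direct	CNV3	present	present	present	present	present	absent
IGHV(II)-31-1	P	92	direct	CNV3	present	present	present	present	present	present
IGHV4-31	F	93	direct	CNV3	present	present	present	present	present	present
IGHV3-30-52	P	94	direct	CNV3	present	absent	present	present	present	present
IGHV(II)-30-51	P	95	direct	CNV3	present	absent	absent	present	present	present
IGHV3-30-5	F	96	direct	CNV3	present	absent	absent	present	present	present
IGHV3-30-42	P	97	direct	CNV3	present	absent	absent	present	present	present
IGHV(II)-30-41	P	98	direct	CNV3	present	absent	present	absent	present	present
IGHV4-30-4	F	99	direct	CNV3	present	absent	present	absent	present	present
IGHV3-30-33	P	100	direct	CNV3	present	absent	present	absent	present	present
IGHV(II)-30-32	P	101	direct	CNV3	present	present	present	absent	absent	present
IGHV3-30-3	F	102	direct	CNV3	present	present	present	absent	absent	present
IGHV3-30-22	P	103	direct	CNV3	present	present	present	absent	absent	present
IGHV(II)-30-21	P	104	direct	CNV3	present	present	present	present	absent	present
IGHV4-30-2	F	105	direct	CNV3	present	present	present	present	absent	present
IGHV4-30-1	F	106	direct	CNV3	present	present	present	present	absent	present
IGHV3-30-2	P	107	direct	CNV3	present	present	present	present	present	present
IGHV(II)-30-1	P	108	direct	CNV3	present	present	present	present	present	present
IGHV3-30	F	109	direct	CNV3	present	present	present	present	present	present
GOLGA4P2	nr	110	direct	CNV3	present	present	present	present	present	present
IGHV3-29	P	111	direct	CNV3	present	present	present	present	present	present
IGHV(II)-28-1	P	112	direct	CNV3	present	present	present	present	present	present
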