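# species: Homo sapiens
# locus: TRG
# haplotype B deletes TRGV4 and TRGV5; haplotype C carries the rare TRGV3P
# insertion between TRGV3 and TRGV4 (absent from the reference haplotype A).
gene_name	functionality	order	orientation	cnv_role	A	B	C
TRGV1	ORF	1	direct		present	present	present
TRGV2	F	2	direct		present	present	present
TRGV3	F	3	direct	CNV1-5prime	present	present	present
TRGV3P	P	4	direct	CNV1=TRGV(4-6)3(2F,1P)	absent	absent	inserted
TRGV4	F	5	direct	CNV1	present	absent	present
TRGV5	F	6	direct	CNV1	present	absent	present
TRGV5P	P	7	direct	CNV1-3prime	present	present	present
TRGV6	P	8	direct		present	present	present
TRGV7	P	9	direct		present	present	present
TRGV8	F	10	direct		present	present	present
TRGVA	P	11	direct		present	present	present
TRGV9	F	12	direct		present	present	present
TRGV10	ORF	13	direct		present	present	present
TRGVB	P	14	direct		present	present	present
TRGV11	ORF	15	direct		present	present	present
TRGJP1	F	16	direct		present	present	present
TRGJP	F	17	direct		present	present	present
TRGJ1	F	18	direct		present	present	present
TRGC1	F	19	direct		present	present	present
TRGJP2	F	20	direct		present	present	present
TRGJ2	F	21	direct		present	present	present
TRGC2	F	22	direct		present	present	present
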