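# species: Homo sapiens
# locus: IGK
# haplotype B lacks the distal V cluster (the single observed deletion
# haplotype); all other genes are shared with haplotype A.
gene_name	functionality	order	orientation	cnv_role	A	B
IGKV1-NL1	F	0	N.d		present	present
IGKV3D-7	F	1	opposite	CNV1=IGKV(1-36)36(16F,4O,14P,1FO,1FP)	present	absent
IGKV1D-8	F	2	opposite	CNV1	present	absent
IGKV1D-43	F	3	opposite	CNV1	present	absent
IGKV1D-42	ORF	4	opposite	CNV1	present	absent
IGKV2D-10	P	5	opposite	CNV1	present	absent
IGKV3D-11	F	6	opposite	CNV1	present	absent
IGKV1D-12	F	7	opposite	CNV1	present	absent
IGKV1D-13	F	8	opposite	CNV1	present	absent
IGKV2D-14	P	9	opposite	CNV1	present	absent
IGKV3D-15	F, P	10	opposite	CNV1	present	absent
IGKV1D-16	F	11	opposite	CNV1	present	absent
IGKV1D-17	F	12	opposite	CNV1	present	absent
IGKV6D-41	ORF	13	opposite	CNV1	present	absent
IGKV2D-18	P	14	opposite	CNV1	present	absent
IGKV2D-19	P	15	opposite	CNV1	present	absent
IGKV3D-20	F, ORF	16	opposite	CNV1	present	absent
IGKV6D-21	F	17	opposite	CNV1	present	absent
IGKV1D-22	P	18	opposite	CNV1	present	absent
IGKV2D-23	P	19	opposite	CNV1	present	absent
IGKV2D-24	ORF	20	opposite	CNV1	present	absent
IGKV3D-25	P	21	opposite	CNV1	present	absent
IGKV2D-26	F	22	opposite	CNV1	present	absent
IGKV1D-27	P	23	opposite	CNV1	present	absent
IGKV2D-28	F	24	opposite	CNV1	present	absent
IGKV2D-29	F	25	opposite	CNV1	present	absent
IGKV2D-30	F	26	opposite	CNV1	present	absent
IGKV3D-31	P	27	opposite	CNV1	present	absent
IGKV1D-32	P	28	opposite	CNV1	present	absent
IGKV1D-33	F	29	opposite	CNV1	present	absent
IGKV3D-34	P	30	opposite	CNV1	present	absent
IGKV1D-35	P	31	opposite	CNV1	present	absent
IGKV2D-36	P	32	opposite	CNV1	present	absent
IGKV1D-37	ORF	33	opposite	CNV1	present	absent
IGKV2D-38	P	34	opposite	CNV1	present	absent
IGKV1D-39	F	35	opposite	CNV1	present	absent
IGKV2D-40	F	36	opposite	CNV1	present	absent
IGKV2-40	F	37	direct		present	present
IGKV1-39	F, P	38	direct		present	present
IGKV2-38	P	39	direct		present	present
IGKV1-37	ORF	40	direct		present	present
IGKV2-36	P	41	direct		present	present
IGKV1-35	P	42	direct		present	present
IGKV3-34	P	43	direct		present	present
IGKV1-33	F	44	direct		present	present
IGKV1-32	P	45	direct		present	present
IGKV3-31	P	46	direct		present	present
IGKV2-30	F	47	direct		present	present
IGKV2-29	F, P	48	direct		present	present
IGKV2-28	F	49	direct		present	present
IGKV1-27	F	50	direct		present	present
IGKV2-26	P	51	direct		present	present
IGKV3-25	P	52	direct		present	present
IGKV2-24	F	53	direct		present	present
IGKV2-23	P	54	direct		present	present
IGKV1-22	P	55	direct		present	present
IGKV6-21	F	56	direct		present	present
IGKV3-20	F	57	direct		present	present
IGKV2-19	P	58	direct		present	present
IGKV2-18	P	59	direct		present	present
IGKV1-17	F	60	direct		present	present
IGKV1-16	F	61	direct		present	present
IGKV3-15	F	62	direct		present	present
IGKV2-14	P	63	direct		present	present
IGKV1-13	F, P	64	direct		present	present
IGKV1-12	F	65	direct		present	present
IGKV3-11	F	66	direct		present	present
IGKV2-10	P	67	direct		present	present
IGKV1-9	F	68	direct		present	present
IGKV1-8	F	69	direct		present	present
IGKV3-7	ORF	70	direct		present	present
IGKV1-6	F	71	direct		present	present
IGKV1-5	F	72	direct		present	present
IGKV2-4	P	73	direct		present	present
IGKV7-3	P	74	direct		present	present
IGKV5-2	F	75	opposite		present	present
IGKV4-1	F	76	opposite		present	present
IGKJ1	F	77	direct		present	present
IGKJ2	F	78	direct		present	present
IGKJ3	F	79	direct		present	present
IGKJ4	F	80	direct		present	present
IGKJ5	F	81	direct		present	present
IGKC	F	82	direct		present	present
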