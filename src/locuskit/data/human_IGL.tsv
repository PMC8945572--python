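# species: Homo sapiens
# locus: IGL
# haplotypes B to E carry one to four additional J-C cassettes (8, 9, 10 or
# 11 IGLJ/IGLC genes); the cassettes sit at dotted orders 88.1-88.8 and are
# absent from the reference haplotype A.
gene_name	functionality	order	orientation	cnv_role	A	B	C	D	E
IGLV(I)-70	P	1	direct		present	present	present	present	present
FRAMENP	nr	2	opposite		present	present	present	present	present
IGLV4-69	F	3	direct		present	present	present	present	present
IGLV(I)-68	P	4	direct		present	present	present	present	present
IGLV10-67	P	5	direct		present	present	present	present	present
IGLV(IV)-66-1	P	6	direct		present	present	present	present	present
IGLV(V)-66	P	7	direct		present	present	present	present	present
IGLV(IV)-65	P	8	direct		present	present	present	present	present
IGLV(IV)-64	P	9	direct		present	present	present	present	present
IGLV(I)-63	P	10	direct		present	present	present	present	present
IGLV1-62	P	11	direct		present	present	present	present	present
IGLV8-61	F	12	direct		present	present	present	present	present
IGLV4-60	F, P	13	direct		present	present	present	present	present
IGLV(IV)-59	P	14	direct		present	present	present	present	present
IGLV(V)-58	P	15	direct		present	present	present	present	present
BMP6P1	nr	16	direct		present	present	present	present	present
IGLV6-57	F	17	direct		present	present	present	present	present
IGLV(I)-56	P	18	direct		present	present	present	present	present
IGLV(IV)-55-1	P	18.1	direct		present	present	present	present	present
IGLV11-55	ORF	19	direct		present	present	present	present	present
IGLV10-54	F, P	20	direct		present	present	present	present	present
IGLV(IV)-53	P	21	direct		present	present	present	present	present
VPREB1	F	22	direct		present	present	present	present	present
IGLV5-52	F	23	direct		present	present	present	present	present
IGLV1-51	F	24	direct		present	present	present	present	present
IGLV1-50	ORF	25	direct		present	present	present	present	present
IGLV9-49	F	26	direct		present	present	present	present	present
IGLV5-48	ORF, P	27	direct		present	present	present	present	present
IGLV1-47	F	28	direct		present	present	present	present	present
IGLV7-46	F, P	29	direct		present	present	present	present	present
IGLV5-45	F	30	direct		present	present	present	present	present
IGLV1-44	F	31	direct		present	present	present	present	present
IGLV7-43	F	32	direct		present	present	present	present	present
IGLV(I)-42	P	33	direct		present	present	present	present	present
IGLV(VII)-41-1	P	34	direct		present	present	present	present	present
IGLV1-41	ORF, P	35	direct		present	present	present	present	present
IGLV1-40	F	36	direct		present	present	present	present	present
IGLV5-39	F	37	direct		present	present	present	present	present
IGLV(I)-38	P	38	direct		present	present	present	present	present
IGLV5-37	F	39	direct		present	present	present	present	present
IGLV1-36	F	40	direct		present	present	present	present	present
IGLV7-35	P	41	direct		present	present	present	present	present
ZNF280B	nr	42	opposite		present	present	present	present	present
ZNF280A	nr	43	opposite		present	present	present	present	present
PRAME	nr	44	opposite		present	present	present	present	present
IGLV2-34	P	45	direct		present	present	present	present	present
IGLV2-33	ORF	46	direct		present	present	present	present	present
IGLV3-32	ORF	47	direct		present	present	present	present	present
IGLV3-31	P	48	direct		present	present	present	present	present
IGLV3-30	P	49	direct		present	present	present	present	present
BCRP4	nr	50	direct		present	present	present	present	present
POM121L1P	nr	51	opposite		present	present	present	present	present
GGTLC2	nr	52	direct		present	present	present	present	present
LOC129026	nr	53	direct		present	present	present	present	present
IGLV3-29	P	54	direct		present	present	present	present	present
IGLV2-28	P	55	direct		present	present	present	present	present
IGLV3-27	F	56	direct		present	present	present	present	present
IGLV3-26	P	57	direct		present	present	present	present	present
IGLV(VI)-25-1	P	58	direct		present	present	present	present	present
IGLV3-25	F	59	direct		present	present	present	present	present
IGLV3-24	P	60	direct		present	present	present	present	present
IGLV2-23	F	61	direct		present	present	present	present	present
IGLV(VI)-22-1	P	62	direct		present	present	present	present	present
IGLV3-22	F, P	63	direct		present	present	present	present	present
IGLV3-21	F	64	direct		present	present	present	present	present
IGLV(I)-20	P	65	direct		present	present	present	present	present
IGLV3-19	F	66	direct		present	present	present	present	present
IGLV2-18	F	67	direct		present	present	present	present	present
IGLV3-17	P	68	direct		present	present	present	present	present
IGLV3-16	F	69	direct		present	present	present	present	present
IGLV3-15	P	70	direct		present	present	present	present	present
IGLV2-14	F	71	direct		present	present	present	present	present
IGLV3-13	P	72	direct		present	present	present	present	present
IGLV3-12	F, P	73	direct		present	present	present	present	present
IGLV(I)-11-1	P	73.1	direct		present	present	present	present	present
IGLV2-11	F	74	direct		present	present	present	present	present
IGLV3-10	F	75	direct		present	present	present	present	present
IGLV3-9	F, P	76	direct		present	present	present	present	present
IGLV2-8	F	77	direct		present	present	present	present	present
IGLV3-7	P	78	direct		present	present	present	present	present
IGLV3-6	P	79	direct		present	present	present	present	present
IGLV2-5	P	80	direct		present	present	present	present	present
IGLV3-4	P	81	direct		present	present	present	present	present
IGLV4-3	F	82	direct		present	present	present	present	present
IGLV3-2	P	83	direct		present	present	present	present	present
IGLV3-1	F	84	direct		present	present	present	present	present
IGLJ1	F	85	direct		present	present	present	present	present
IGLC1	F, ORF	86	direct		present	present	present	present	present
IGLJ2	F	87	direct		present	present	present	present	present
IGLC2	F	88	direct	CNV1-5prime	present	present	present	present	present
IGLJ2A	N.d	88.1	direct	CNV1=IGLJ-IGLC(88-89)8(N.d)	absent	inserted	inserted	inserted	inserted
IGLC2A	N.d	88.2	direct	CNV1	absent	inserted	inserted	inserted	inserted
IGLJ2B	N.d	88.3	direct	CNV1	absent	absent	inserted	inserted	inserted
IGLC2B	N.d	88.4	direct	CNV1	absent	absent	inserted	inserted	inserted
IGLJ2C	N.d	88.5	direct	CNV1	absent	absent	absent	inserted	inserted
IGLC2C	N.d	88.6	direct	CNV1	absent	absent	absent	inserted	inserted
IGLJ2D	N.d	88.7	direct	CNV1	absent	absent	absent	absent	inserted
IGLC2D	N.d	88.8	direct	CNV1	absent	absent	absent	absent	inserted
IGLJ3	F	89	direct	CNV1-3prime	present	present	present	present	present
IGLC3	F	90	direct		present	present	present	present	present
IGLJ4	ORF	91	direct		present	present	present	present	present
IGLC4	P	92	direct		present	present	present	present	present
IGLJCBN5	ORF	93	direct		present	present	present	present	present
IGLC5	P	94	direct		present	present	present	present	present
IGLJ6	F	95	direct		present	present	present	present	present
IGLC6	F, P	96	direct		present	present	present	present	present
IGLJ7	F	97	direct		present	present	present	present	present
IGLC7	F	98	direct		present	present	present	present	present
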