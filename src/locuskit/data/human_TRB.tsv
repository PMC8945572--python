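# species: Homo sapiens
# locus: TRB
# haplotype B carries the 21 kb V-gene deletion (TRBV3-2, TRBV4-3, TRBV6-3)
# and the trypsinogen-like deletion of T7 and T8.
gene_name	functionality	order	orientation	cnv_role	A	B
TRBV1	P	3	direct		present	present
TRBV2	F	4	direct		present	present
TRBV3-1	F	5	direct		present	present
TRBV4-1	F	6	direct		present	present
TRBV5-1	F	7	direct		present	present
TRBV6-1	F	8	direct		present	present
TRBV7-1	ORF	9	direct		present	present
TRBV4-2	F	10	direct	CNV1-5prime	present	present
TRBV6-2	F	11	direct	CNV1=TRBV(11-14)4(3F,1P)	present	present
TRBV3-2	P	12	direct	CNV1	present	absent
TRBV4-3	F	13	direct	CNV1	present	absent
TRBV6-3	F	14	direct	CNV1	present	absent
TRBV7-2	F	15	direct	CNV1-3prime	present	present
TRBV8-1	P	16	direct		present	present
TRBV5-2	P	17	direct		present	present
TRBV6-4	F	18	direct		present	present
TRBV7-3	F, ORF	19	direct		present	present
TRBV8-2	P	20	direct		present	present
TRBV5-3	ORF	21	direct		present	present
TRBV9	F	22	direct		present	present
TRBV10-1	F, P	23	direct		present	present
TRBV11-1	F	24	direct		present	present
TRBV12-1	P	25	direct		present	present
TRBV10-2	F	26	direct		present	present
TRBV11-2	F	27	direct		present	present
TRBV12-2	P	28	direct		present	present
TRBV6-5	F	29	direct		present	present
TRBV7-4	F, P	30	direct		present	present
TRBV5-4	F	31	direct		present	present
TRBV6-6	F	32	direct		present	present
TRBV7-5	P	33	direct		present	present
TRBV5-5	F	34	direct		present	present
TRBV6-7	ORF	35	direct		present	present
TRBV7-6	F	36	direct		present	present
TRBV5-6	F	37	direct		present	present
TRBV6-8	F	38	direct		present	present
TRBV7-7	F	39	direct		present	present
TRBV5-7	ORF	40	direct		present	present
TRBV6-9	F	41	direct		present	present
TRBV7-8	F	42	direct		present	present
TRBV5-8	F	43	direct		present	present
TRBV7-9	F	44	direct		present	present
TRBV13	F	45	direct		present	present
TRBV10-3	F	46	direct		present	present
TRBV11-3	F	47	direct		present	present
TRBV12-3	F	48	direct		present	present
TRBV12-4	F	49	direct		present	present
TRBV12-5	F	50	direct		present	present
TRBV14	F	51	direct		present	present
TRBV15	F	52	direct		present	present
TRBV16	F, P	53	direct		present	present
TRBV17	ORF	54	direct		present	present
TRBV18	F	55	direct		present	present
TRBV19	F	56	direct		present	present
TRBV20-1	F	57	direct		present	present
TRBV21-1	P	58	direct		present	present
TRBV22-1	P	59	direct		present	present
TRBV23-1	ORF	60	direct		present	present
TRBV24-1	F	61	direct		present	present
TRBV25-1	F	62	direct		present	present
TRBVA	P	63	direct		present	present
TRBV26	P	64	direct		present	present
TRBVB	P	65	direct		present	present
TRBV27	F	66	direct		present	present
TRBVC	P	67	opposite		present	present
TRBV28	F	68	direct		present	present
TRBV29-1	F	69	direct	CNV2-5prime	present	present
T4	nr	70	direct	CNV2=T4-T8(70-74)5(nr)	present	present
T5	nr	71	direct	CNV2	present	present
T6	nr	72	direct	CNV2	present	present
T7	nr	73	direct	CNV2	present	absent
T8	nr	74	direct	CNV2	present	absent
TRBD1	F	75	direct	CNV2-3prime	present	present
TRBJ1-1	F	76	direct		present	present
TRBJ1-2	F	77	direct		present	present
TRBJ1-3	F	78	direct		present	present
TRBJ1-4	F	79	direct		present	present
TRBJ1-5	F	80	direct		present	present
TRBJ1-6	F	81	direct		present	present
TRBC1	F	82	direct		present	present
TRBD2	F	83	direct		present	present
TRBJ2-1	F	84	direct		present	present
TRBJ2-2	F	85	direct		present	present
TRBJ2-2P	ORF	86	direct		present	present
TRBJ2-3	F	87	direct		present	present
TRBJ2-4	F	88	direct		present	present
TRBJ2-5	F	89	direct		present	present
TRBJ2-6	F	90	direct		present	present
TRBJ2-7	F	91	direct		present	present
TRBC2	F	92	direct		present	present
TRBV30	F, P	93	opposite		present	present
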