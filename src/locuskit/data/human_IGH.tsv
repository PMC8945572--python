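# species: Homo sapiens
# locus: IGH
# transcription note: IGHV(III)-2-1 is recorded at order 158; the source table
# prints 581 between 157 and 159, an obvious digit transposition (orders are
# strictly increasing).
gene_name	functionality	order	orientation	cnv_role
IGHV1-NL1	P	0	N.d	
IGHV3-NL1	F	0	N.d	
IGHV7-NL1	P	0	N.d	
IGHV(III)-82	P	1	direct	
IGHV7-81	ORF	2	direct	
IGHV4-80	P	3	direct	
IGHV3-79	P	4	direct	
IGHV(II)-78-1	P	5	direct	
IGHV5-78	P	6	direct	
IGHV7-77	N.d	7	direct	
IGHV(III)-76-1	P	8	direct	
IGHV3-76	P	9	direct	
IGHV3-75	P	10	direct	
IGHV(II)-74-1	P	11	direct	
IGHV3-74	F	12	direct	
IGHV3-73	F	13	direct	
IGHV3-72	F	14	direct	
IGHV3-71	P	15	direct	
IGHV2-70	F, ORF	16	direct	CNV1-5prime
IGHV1-69D	F	17	direct	CNV1=IGHV(17-20)7(3F,4P)
IGHV1-68D	P	17.1	direct	CNV1
IGHV(III)-67-4D	P	17.2	direct	CNV1
IGHV(III)-67-3D	P	17.3	direct	CNV1
IGHV1-69-2	F	18	direct	CNV1
IGHV3-69-1	P	19	direct	CNV1
IGHV2-70D	F	20	direct	CNV1
IGHV1-69	F	21	direct	CNV1-3prime
IGHV1-68	P	22	direct	
IGHV(III)-67-4	P	23	direct	
IGHV(III)-67-3	P	24	direct	
IGHV(III)-67-2	P	25	direct	
IGHV(II)-67-1	P	26	direct	
SLC20A1P1	nr	27	direct	
IGHV1-67	P	28	direct	
IGHV3-66	F	29	direct	
IGHV(II)-65-1	P	30	direct	
IGHV3-65	P	31	direct	
IGHV3-64	F	32	direct	
GOLGA4P3	nr	33	direct	
IGHV3-63	P	34	direct	
IGHV(II)-62-1	P	35	direct	
IGHV3-62	F, P	36	direct	
IGHV4-61	F, ORF	37	direct	
IGHV(II)-60-1	P	38	direct	
IGHV3-60	P	39	direct	
IGHV4-59	F	40	direct	
IGHV1-58	F	41	direct	
IGHV3-57	P	42	direct	
IGHV7-56	P	43	direct	
IGHV4-55	P	44	direct	
IGHV3-54	P	45	direct	
IGHV(II)-53-1	P	46	direct	
IGHV3-53	F	47	direct	
IGHV3-52	P	48	direct	
IGHV(II)-51-2	P	49	direct	
IGHV8-51-1	ORF, P	50	direct	
IGHV5-51	F	51	direct	
IGHV3-50	P	52	direct	
IGHV(II)-49-1	P	53	direct	
IGHV3-49	F	54	direct	
IGHV3-48	F	55	direct	
IGHV(III)-47-1	P	56	direct	
IGHV3-47	P	57	direct	
IGHV(II)-46-1	P	58	direct	
IGHV1-46	F	59	direct	
IGHV1-45	F	60	direct	
IGHV(II)-44-2	P	61	direct	
IGHV(IV)-44-1	P	62	direct	
IGHV(III)-44	P	63	direct	
IGHV(II)-43-1	P	64	direct	
IGHV3-43	F	65	direct	
IGHV3-42	P	66	direct	
IGHV3-41	P	67	direct	
IGHV(II)-40-1	P	68	direct	
IGHV7-40	P	69	direct	
IGHV4-39	F	70	direct	CNV2-5prime
IGHV1-38-4	ORF	71	direct	CNV2=IGHV(71-80)10(2F,2O,6P)
IGHV(III)-38-1D	P	72	direct	CNV2
IGHV3-38-3	ORF	73	direct	CNV2
IGHV(III)-44D	P	74	direct	CNV2
IGHV(II)-43-1D	P	75	direct	CNV2
IGHV3-43D	F	76	direct	CNV2
IGHV3-42D	P	77	direct	CNV2
IGHV7-40D	P	78	direct	CNV2
IGHV4-38-2	F	79	direct	CNV2
IGHV(III)-38-1	P	80	direct	CNV2
IGHV3-38	ORF	81	direct	CNV2-3prime
IGHV3-37	P	82	direct	
IGHV3-36	P	83	direct	
IGHV3-35	F, ORF	84	direct	
IGHV7-34-1	P	85	direct	
IGHV4-34	F	86	direct	CNV3-5prime
IGHV3-33-2	P	87	direct	CNV3=IGHV(87-112)26(8F,16P,2RPI)
IGHV(II)-33-1	P	88	direct	CNV3
IGHV3-33	F	89	direct	CNV3
GOLGA4P1	nr	90	direct	CNV3
IGHV3-32	P	91	direct	CNV3
IGHV(II)-31-1	P	92	direct	CNV3
IGHV4-31	F	93	direct	CNV3
IGHV3-30-52	P	94	direct	CNV3
IGHV(II)-30-51	P	95	direct	CNV3
IGHV3-30-5	F	96	direct	CNV3
IGHV3-30-42	P	97	direct	CNV3
IGHV(II)-30-41	P	98	direct	CNV3
IGHV4-30-4	F	99	direct	CNV3
IGHV3-30-33	P	100	direct	CNV3
IGHV(II)-30-32	P	101	direct	CNV3
IGHV3-30-3	F	102	direct	CNV3
IGHV3-30-22	P	103	direct	CNV3
IGHV(II)-30-21	P	104	direct	CNV3
IGHV4-30-2	F	105	direct	CNV3
IGHV4-30-1	F	106	direct	CNV3
IGHV3-30-2	P	107	direct	CNV3
IGHV(II)-30-1	P	108	direct	CNV3
IGHV3-30	F	109	direct	CNV3
GOLGA4P2	nr	110	direct	CNV3
IGHV3-29	P	111	direct	CNV3
IGHV(II)-28-1	P	112	direct	CNV3
IGHV4-28	F	113	direct	CNV3-3prime
IGHV7-27	P	114	direct	
IGHV(II)-26-2	P	115	direct	
IGHV(III)-26-1	P	116	direct	
IGHV2-26	F	117	direct	
IGHV(III)-25-1	P	118	direct	
IGHV3-25	ORF, P	119	direct	
IGHV1-24	F	120	direct	CNV4-5prime
IGHV3-23D	F	121	direct	CNV4=IGHV(121-123)3(1F,2P)
IGHV(III)-22-2D	P	122	direct	CNV4
IGHV(II)-22-1D	P	123	direct	CNV4
IGHV3-23	F	124	direct	CNV4-3prime
IGHV(III)-22-2	P	125	direct	
IGHV(II)-22-1	P	126	direct	
IGHV3-22	P	127	direct	
IGHV3-21	F	128	direct	
IGHV(II)-20-1	P	129	direct	
IGHV3-20	F, ORF	130	direct	
IGHV3-19	P	131	direct	
IGHV1-18	F	132	direct	
SLC20A1P2	nr	133	direct	
IGHV1-17	P	134	direct	
IGHV(III)-16-1	P	135	direct	
IGHV3-16	ORF	136	direct	
IGHV(II)-15-1	P	137	direct	
IGHV3-15	F	138	direct	
IGHV1-14	P	139	direct	
IGHV(III)-13-1	P	140	direct	
IGHV3-13	F	141	direct	
IGHV1-12	P	142	direct	
IGHV(III)-11-1	P	143	direct	
IGHV3-11	F, P	144	direct	CNV5-5prime
IGHV2-10	P	145	direct	CNV5=IGHV(145-149)5(4F,1P)
IGHV3-9	F	146	direct	CNV5
IGHV1-8	F	147	direct	CNV5
IGHV5-10-1	F	148	direct	CNV5
IGHV3-64D	F	149	direct	CNV5
IGHV3-7	F	150	direct	CNV5-3prime
IGHV3-6	P	151	direct	
IGHV(III)-5-2	P	152	direct	
IGHV(III)-5-1	P	153	direct	
IGHV2-5	F	154	direct	CNV6-5prime
IGHV7-4-1	F	155	direct	CNV6=IGHV(155)1(1F)
IGHV4-4	F	156	direct	CNV6-3prime
IGHV1-3	F	157	direct	
IGHV(III)-2-1	P	158	direct	
IGHV1-2	F	159	direct	
RPS8P1	nr	160	direct	
ADAM6	nr	161	direct	
IGHV(II)-1-1	P	162	direct	
IGHV6-1	F, P	163	direct	
FAM30A	nr	164	opposite	
IGHD1-1	F	165	direct	
IGHD2-2	F	166	direct	
IGHD3-3	F	167	direct	
IGHD4-4	F	168	direct	
IGHD5-5	F	169	direct	
IGHD6-6	F	170	direct	
IGHD1-7	F	171	direct	
IGHD2-8	F	172	direct	
IGHD3-9	F	173	direct	
IGHD3-10	F	174	direct	
IGHD4-11	ORF	175	direct	
IGHD5-12	F	176	direct	
IGHD6-13	F	177	direct	
IGHD1-14	ORF	178	direct	
IGHD2-15	F	179	direct	
IGHD3-16	F	180	direct	
IGHD4-17	F	181	direct	
IGHD5-18	F	182	direct	
IGHD6-19	F	183	direct	
IGHD1-20	F	184	direct	
IGHD2-21	F	185	direct	
IGHD3-22	F	186	direct	
IGHD4-23	ORF	187	direct	
IGHD5-24	ORF	188	direct	
IGHD6-25	F	189	direct	
IGHD1-26	F	190	direct	
IGHJ1P	P	191	direct	
IGHD7-27	F	192	direct	
IGHJ1	F	193	direct	
IGHJ2	F	194	direct	
IGHJ2P	P	195	direct	
IGHJ3	F	196	direct	
IGHJ4	F	197	direct	
IGHJ5	F	198	direct	
IGHJ3P	P	199	direct	
IGHJ6	F	200	direct	
IGHM	F	201	direct	
IGHD	F	202	direct	CNV7-5prime
IGHG3	F	203	direct	CNV7=IGHC(203-211)9(7F,1OP,1P)
IGHG1	F	204	direct	CNV7
IGHEP1	P	205	direct	CNV7
IGHA1	F	206	direct	CNV7
IGHGP	ORF, P	207	direct	CNV7
IGHG2	F	208	direct	CNV7
IGHG4	F	209	direct	CNV7
IGHE	F	210	direct	CNV7
IGHA2	F	211	direct	CNV7
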