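# species: Homo sapiens
# locus: TRA/TRD
gene_name	functionality	order	orientation	cnv_role
TRAV1-1	F	1	direct	
TRAV1-2	F	2	direct	
TRAV2	F	3	direct	
TRAV3	F, P	4	direct	
TRAV4	F	5	direct	
TRAV5	F	6	direct	
TRAV6	F	7	direct	
TRAV7	F	8	direct	
TRAVA	P	9	direct	
TRAV8-1	F	10	direct	
TRAV9-1	F	11	direct	
TRAV10	F	12	direct	
TRAV11	P	13	direct	
TRAV12-1	F	14	direct	
TRAV8-2	F	15	direct	
TRAV8-3	F	16	direct	
TRAVB	P	17	direct	
TRAV13-1	F	18	direct	
TRAV14-1	P	19	direct	
TRAV11-1	P	20	direct	
TRAV12-2	F	21	direct	
TRAV8-4	F	22	direct	
TRAV8-5	P	23	direct	
TRAV13-2	F	24	direct	
TRAV14/DV4	F	25	direct	
TRAV9-2	F	26	direct	
TRAV15	P	27	direct	
TRAV12-3	F	28	direct	
TRAV8-6	F	29	direct	
TRAV16	F	30	direct	
TRAV17	F	31	direct	
TRAV18	F	32	direct	
TRAV19	F	33	direct	
TRAVC	P	34	direct	
TRAV20	F	35	direct	
TRAV21	F	36	direct	
TRAV8-6-1	P	37	direct	
TRAV22	F	38	direct	
TRAV23/DV6	F	39	direct	
TRDV1	F	40	direct	
TRAV24	F	41	direct	
TRAV25	F	42	direct	
TRAV26-1	F	43	direct	
TRAV8-7	P	44	direct	
TRAV27	F	45	direct	
TRAV28	P	46	direct	
TRAV29/DV5	F, P	47	direct	
TRAV30	F	48	direct	
TRAV31	P	49	direct	
TRAV32	P	50	direct	
TRAV33	P	51	direct	
TRAV26-2	F	52	direct	
TRAV34	F	53	direct	
TRAV35	F, P	54	direct	
TRAV36/DV7	F	55	direct	
TRAV37	P	56	direct	
TRAV38-1	F	57	direct	
TRAV38-2/DV8	F	58	direct	
TRAV39	F	59	direct	
TRAV40	F	60	direct	
TRAV41	F	61	direct	
TRAV46	P	62	direct	
TRDV2	F	63	direct	
TRDD1	F	64	direct	
TRDD2	F	65	direct	
TRDD3	F	66	direct	
TRDJ1	F	67	direct	
TRDJ4	F	68	direct	
TRDJ2	F	69	direct	
TRDJ3	F	70	direct	
TRDC	F	71	direct	
TRDV3	F	72	opposite	
TRAJ61	ORF	73	direct	
TRAJ60	P	74	direct	
TRAJ59	ORF	75	direct	
TRAJ58	ORF	76	direct	
TRAJ57	F	77	direct	
TRAJ56	F	78	direct	
TRAJ55	P	79	direct	
TRAJ54	F	80	direct	
TRAJ53	F	81	direct	
TRAJ52	F	82	direct	
TRAJ51	P	83	direct	
TRAJ50	F	84	direct	
TRAJ49	F	85	direct	
TRAJ48	F	86	direct	
TRAJ47	F	87	direct	
TRAJ46	F	88	direct	
TRAJ45	F	89	direct	
TRAJ44	F	90	direct	
TRAJ43	F	91	direct	
TRAJ42	F	92	direct	
TRAJ41	F	93	direct	
TRAJ40	F	94	direct	
TRAJ39	F	95	direct	
TRAJ38	F	96	direct	
TRAJ37	F	97	direct	
TRAJ36	F	98	direct	
TRAJ35	F	99	direct	
TRAJ34	F	100	direct	
TRAJ33	F	101	direct	
TRAJ32	F	102	direct	
TRAJ31	F	103	direct	
TRAJ30	F	104	direct	
TRAJ29	F	105	direct	
TRAJ28	F	106	direct	
TRAJ27	F	107	direct	
TRAJ26	F	108	direct	
TRAJ25	ORF	109	direct	
TRAJ24	F	110	direct	
TRAJ23	F	111	direct	
TRAJ22	F	112	direct	
TRAJ21	F	113	direct	
TRAJ20	F	114	direct	
TRAJ19	ORF	115	direct	
TRAJ18	F	116	direct	
TRAJ17	F	117	direct	
TRAJ16	F	118	direct	
TRAJ15	F	119	direct	
TRAJ14	F	120	direct	
TRAJ13	F	121	direct	
TRAJ12	F	122	direct	
TRAJ11	F	123	direct	
TRAJ10	F	124	direct	
TRAJ9	F	125	direct	
TRAJ8	F, P	126	direct	
TRAJ7	F	127	direct	
TRAJ6	F	128	direct	
TRAJ5	F	129	direct	
TRAJ4	F	130	direct	
TRAJ3	F	131	direct	
TRAJ2	ORF	132	direct	
TRAJ1	ORF	133	direct	
TRAC	F	134	direct	
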