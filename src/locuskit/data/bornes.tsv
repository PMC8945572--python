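# Locus 5'/3' bornes: conserved non-IG/TR genes flanking each locus, with the
# number of annotated species in which each borne is observed.
locus	side	gene_name	gene_description	occurrence
IGH	5prime	N.d.		6/6
IGH	3prime	N.d.		6/6
IGK	5prime	PAX8	paired box 8	6/10
IGK	5prime	N.d.		4/10
IGK	3prime	RPIA	ribose 5-phosphate isomerase A	10/10
IGL	5prime	TOP3B	DNA topoisomerase III	4/9
IGL	5prime	SLC5A1	solute carrier family 5 member 1	2/9
IGL	5prime	N.d.		3/9
IGL	3prime	RSPH14	radial spoke head 14 homolog	5/9
IGL	3prime	VPREB3	V-set pre-B cell surrogate light chain 3	3/9
IGL	3prime	N.d.		1/9
TRA/TRD	5prime	OR10G3	olfactory receptor 10G3	6/9
TRA/TRD	5prime	N.d.		3/9
TRA/TRD	3prime	DAD1	defender against cell death	9/9
TRB	5prime	MOXD2	monooxygenase DBH-like 2	10/10
TRB	3prime	EPHB6	EPH receptor B6	10/10
TRG	5prime	AMPH	amphiphysin	8/8
TRG	3prime	STARD3NL	STARD3 N-terminal like	8/8
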