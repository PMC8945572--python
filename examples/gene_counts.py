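"""Count genes per type in the human locus tables.

Reproduces the headline per-locus totals: 27 diversity and 9 joining genes in
the heavy-chain locus, 76 kappa V genes split 36 distal / 40 proximal, and 61
alpha joining genes (the unusually large TRAJ set).
"""

from locuskit import count_genes, fixtures, gene_filter

igh = fixtures.load_human("IGH")
igk = fixtures.load_human("IGK")
tra = fixtures.load_human("TRA")

print("IGHD genes:", count_genes(igh, gene_filter(gene_type="D")))
print("IGHJ genes:", count_genes(igh, gene_filter(gene_type="J")))
print("IGHC genes:", count_genes(igh, gene_filter(gene_type="C")))
print("IGKV genes:", count_genes(igk, gene_filter(gene_type="V")),
      "(distal", count_genes(igk, lambda r: r.name.gene_type == "V" and r.order.major <= 36),
      "+ proximal", count_genes(igk, lambda r: r.name.gene_type == "V" and r.order.major > 36),
      ")")
print("TRAJ genes:", count_genes(tra, gene_filter(gene_type="J", locus="TRA")))
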