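"""Diff locus haplotypes against the reference haplotype A.

Haplotype A is the conventional main line; other haplotypes differ by gene
insertions (i) and deletions (d).  The beta-locus haplotype B deletes a
three-V-gene block plus two trypsinogen-like marker genes; the lambda
haplotypes carry one to four extra J-C cassettes, so the constant-gene count
ranges from 7 to 11.
"""

from locuskit import (
    diff_haplotypes,
    fixtures,
    gene_filter,
    haplotype_gene_count,
    haplotype_range_summary,
)

trb = fixtures.load_human_haplotypes("TRB")
diff = diff_haplotypes(trb, "A", "B")
print("TRB haplotype B vs A deletions:", ", ".join(diff.genes("d")))

igl = fixtures.load_human_haplotypes("IGL")
for h in igl.haplotype_ids:
    n = haplotype_gene_count(igl, h, gene_filter(gene_type="C"))
    print(f"IGL haplotype {h}: {n} constant genes")
print("IGLC count range over haplotypes:",
      haplotype_range_summary(igl, gene_filter(gene_type="C")))
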