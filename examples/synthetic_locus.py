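"""Generate a seeded synthetic locus and validate it.

The generator emulates the canonical V-D-J-C organization with configurable
gene counts, functionality mix, interspersed marker genes, dotted insertion
orders and per-haplotype indels.  The same seed always reproduces the same
locus; the emitted table passes the fixture validator.
"""

import tempfile
from pathlib import Path

from locuskit import GeneratorConfig, diff_haplotypes, generate_locus, save_gene_order, validate_fixture

cfg = GeneratorConfig(seed=42, n_v=30, n_haplotypes=4)
table, haplotypes = generate_locus(cfg)

print(f"generated {len(table)} genes for locus {table.locus}, "
      f"haplotypes {haplotypes.haplotype_ids}")
for h in haplotypes.haplotype_ids[1:]:
    d = diff_haplotypes(haplotypes, "A", h)
    print(f"  haplotype {h}: {len(d.genes('d'))} deleted, {len(d.genes('i'))} inserted vs A")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "synthetic.tsv"
    save_gene_order(table, path)
    print("validator:", validate_fixture(path))
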