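"""Derive standardized CNV definitions from the human heavy-chain table.

Loads the packaged IGH gene-order table and derives the V-gene CNV between
its published delimiters.  The printed string packs the span (gene orders of
the first and last member), the total member count, and a tally by
functionality: 3 functional genes and 4 pseudogenes between IGHV2-70 and
IGHV1-69.
"""

from locuskit import CnvBoundary, cnv_id, derive_cnv_definition, fixtures, format_cnv_definition

igh = fixtures.load_human("IGH")

d = derive_cnv_definition(igh, CnvBoundary.of("IGHV2-70", "IGHV1-69"), number=1)
print(cnv_id("Homo sapiens", "IGH", 1), "=", format_cnv_definition(d))

d3 = derive_cnv_definition(igh, CnvBoundary.of("IGHV4-34", "IGHV4-28"), number=3)
print(cnv_id("Homo sapiens", "IGH", 3), "=", format_cnv_definition(d3))
print(f"  {d3.total} genes in the span, of which {d3.counts['RPI']} are "
      "interspersed non-IG/TR marker genes (golgin pseudogenes)")
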