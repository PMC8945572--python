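"""Render and re-parse a locus-unit flat-file record.

Builds the rhesus macaque IGL locus record (a reverse-orientation locus of
1,300,711 bp on chromosome 10) and prints its feature-table fragment: the ten
standardized qualifiers in byte-wise name order, wrapped at 80 columns, plus
the definition line carrying the assembly provenance.
"""

from locuskit import (
    fixtures,
    make_locus_id,
    parse_locus_unit,
    render_definition_line,
    render_locus_unit,
)

assembly, unit, accession = fixtures.macmul_igl_locus_unit()

print("locus ID:", make_locus_id("Macaca", "mulatta", "IGL", 2))
for line in render_locus_unit(unit):
    print(line)
print()
print(render_definition_line(assembly, unit, accession))

reparsed = parse_locus_unit(render_locus_unit(unit))
print("\nround-trip intact:", reparsed == unit)
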