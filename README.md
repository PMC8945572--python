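# locuskit

A library (with a thin `locuskit` CLI) implementing the data model of the
immunoglobulin (IG) and T cell receptor (TR) loci — the seven antigen-receptor
loci of higher vertebrates: IGH, IGK, IGL for the immunoglobulins, TRA, TRB,
TRG and TRD for the T cell receptors (TRD nestled inside TRA).  It is aimed at
immunogenetics biocurators and tool authors who need the *locus-level*
semantics those loci share: standardized gene symbols, gene order, copy number
variation (CNV) definitions, haplotype representation, locus-unit flat-file
records and chromosome/locus coordinate mapping.

## What it models

**Gene symbols.** An IG/TR symbol decomposes as locus code + gene type (V, D,
J, C) + designation: a numeric subgroup or a parenthesized Roman-numeral clan
for V genes, hyphen-separated localization numbers (counted 3'→5' in the
locus), duplicate markers (`IGHV1-69D`, `IGKV1D-8`), hybrid alpha/delta
symbols (`TRAV14/DV4`), and the heavy-chain isotype constants written without
a type letter (`IGHM`, `IGHG3`, bare `IGHD` — a C gene, unlike `IGHD1-1`).
Parsing and formatting are exact inverses over every symbol of the shipped
human tables.  Non-IG/TR marker genes interspersed in a locus (golgin
pseudogenes, trypsinogen-like genes, ...) are first-class *RPI* records.

**Gene order.** Each gene has a relative 5'→3' position; dotted decimals
(17.1) number insertions against a reference ruler, 0 marks an unknown
position.  Order-0 genes are excluded from all counts and spans.

**CNV definitions.** A CNV is a segment whose gene content varies between
haplotypes, delimited by a 5' and a 3' gene and summarized as
`<group>(<start>-<end>)<total>(<counts>)` — e.g. the heavy-chain V CNV
`IGHV(17-20)7(3F,4P)`: orders 17–20, 7 genes, 3 functional + 4 pseudogenes.
Dual functionality counts as a single unit (`1OP`), all-marker spans collapse
to `nr`, undetermined spans to `N.d`.  `derive_cnv_definition` computes a
definition from a table and delimiters; `parse_cnv_definition` and
`format_cnv_definition` are inverses on the structured form.

**Haplotypes.** Haplotype A is the reference main line; others are described
by per-gene presence (`present` / `absent` / `inserted`).  Diffs report
status letters i / d / e, and counts obey
`|present(h)| = |present(A)| − #d + #i`.

**Locus units and coordinates.** The ten-qualifier `IMGT-LOCUS-UNIT`
feature-table fragment (EMBL layout: key at column 6, qualifiers at column
22, wrap at 80) with locus IDs such as `Macmul_IGL_2`, plus 1-based-inclusive
mapping between chromosome and locus coordinates for forward (FWD) and
reverse (REV) loci.

The complete human gene-order tables for all seven loci ship as TSV fixtures
(`locuskit.fixtures`), together with the locus-borne table and the
heavy-chain CNV haplotype panels.

## Worked example

```python
from locuskit import CnvBoundary, derive_cnv_definition, format_cnv_definition, fixtures

igh = fixtures.load_human("IGH")
d = derive_cnv_definition(igh, CnvBoundary.of("IGHV4-34", "IGHV4-28"))
print(format_cnv_definition(d))
```

prints

```
IGHV(87-112)26(8F,16P,2RPI)
```

— between the delimiters IGHV4-34 and IGHV4-28 the heavy-chain locus carries
26 genes at orders 87–112: 8 functional V genes, 16 V pseudogenes, and 2
interspersed golgin marker genes.  The same derivation is available from the
shell:

```
locuskit cnv derive --table src/locuskit/data/human_IGH.tsv \
    --5prime IGHV4-34 --3prime IGHV4-28
```

More narrative scripts live in `examples/` (one per capability: CNV
derivation, gene counting, haplotype diffing, flat-file round-trip,
coordinate mapping, synthetic locus generation).

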