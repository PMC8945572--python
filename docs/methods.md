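# Methods

## Scope and model

locuskit models the locus-level organization of the seven human IG/TR loci
and the generic machinery behind it: a gene-order table is an ordered list of
records `(symbol, functionality, order, orientation)`, over which counting,
CNV derivation and haplotype comparison are defined.  Nucleotide sequences
are deliberately out of scope — no alleles, no alignment, no sequence
extraction; coordinate mapping is positional bookkeeping only.

## The symbol grammar

IG/TR symbols are parsed as locus code (3 letters) + gene type (V/D/J/C) +
designation.  Structural choices worth recording:

- **Tokens are kept verbatim.**  The designation is stored as the tuple of
  hyphen-separated tokens; views (`subgroup`, `localization`,
  `duplicate_flag`) are derived.  This guarantees `format(parse(s)) == s`
  exactly, including provisional letters (`TRAVA`), distal duplicates
  (`IGKV1D-8`), pseudogene suffixes that are part of the designation and not
  a functionality marker (`TRGV3P`, `IGHJ1P`), and not-localized designations
  (`IGHV3-NL1`).
- **Heavy-chain isotype constants** (`IGHM`, `IGHD`, `IGHE`, `IGHG3`,
  `IGHGP`, `IGHEP1`, `IGHA2`, ...) print no "C" type letter.  A dedicated
  branch recognizes the isotype shapes so bare `IGHD` is a constant gene
  while `IGHD1-1` is a diversity gene; without this the heavy-chain D count
  would be off by one.
- **V/D tokens are validated strictly** (`\d+[DP]?`, `NL\d+`, or a single
  capital); J/C designations accept a free alphanumeric tail, which lets
  irregular table symbols (e.g. `IGLJCBN5`) parse as joining genes and
  round-trip rather than fall out of the model.
- Any symbol matching no IG/TR pattern is an opaque RPI record.  This is by
  construction total: parsing never fails on a non-empty symbol.

## Gene order

Orders are `(major, minor)` pairs with lexicographic comparison, so dotted
insertion orders sort between their integer neighbours (17 < 17.1 < 18).
`major == 0` means position unknown; such genes are retained in tables but
excluded from every count, span and CNV computation, and are the only rows
allowed the orientation value `N.d`.  The shipped heavy-chain fixture records
`IGHV(III)-2-1` at order 158 (its source table prints 581 between 157 and
159, an evident digit transposition; orders must be strictly increasing —
noted in the fixture header).

## CNV derivation and rendering

Members of a CNV are all positioned records strictly between the 5' and 3'
delimiters, IG/TR and RPI alike.  The tally maps compact codes (F, O, P; FO,
FP, OP for dual calls; RPI for markers) to member counts, with two collapse
rules: an all-RPI span renders the sentinel `nr`, a span whose IG/TR members
are all of undetermined functionality renders `N.d`.  Conservation
(`total == Σ counts`) is enforced at construction and at parse time.

Rendering choices where published usage is not uniform:

- **Count order** is canonical F, O, P, FO, FP, OP, RPI; published strings
  are not consistently ordered, so string comparison (`cnv_strings_equivalent`)
  is order-insensitive over the parsed structure.
- **Dotted spans.**  Cassette insertions sitting between two integer orders
  (the lambda J-C cassettes at 88.1–88.8) render as the integer bracket
  `(88-89)`; the structured form keeps the exact dotted span.  As a
  consequence `parse ∘ format` is the identity for integer-span definitions
  (asserted for all published strings and randomized instances) but not for
  the one dotted-span case, whose printed reproduction is asserted
  separately.
- **Missing 3' delimiter.**  The heavy-chain constant CNV has no 3' delimiter
  (the locus has no identified 3' borne); the boundary type allows an absent
  3' side with an explicit end order.  Spans with no delimiter at all (the
  kappa distal cluster, which starts at the first positioned gene of the
  locus) are derived over an explicit inclusive order span
  (`derive_cnv_span`).
- **Group labels** are auto-derived: shared locus+type of the IG/TR members
  (`IGHV`); J and C members of one locus (`IGLJ-IGLC`); all-RPI spans take
  `<first>-<last>` member names (`T4-T8`).  An explicit label overrides.
- The parser tolerates stray spaces inside a counts list; the serializer
  never emits them.

## Haplotypes

Presence is one of `present`, `absent`, `inserted` (carried although absent
in the reference haplotype A), plus `exchanged`, which is representable and
exercised synthetically but has no observed instance in the human tables.
Invariants enforced at construction: haplotype A exists, A is never
`inserted`, and a gene `inserted` anywhere is `absent` in A.  Diffs against A
report i/d/e letters; the count identity
`|present(h)| = |present(A)| − #d + #i` is a test invariant on fixtures and
synthetic tables.

The published haplotype panels are color-coded figures; the shipped fixtures
encode them as explicit presence values reconstructed from the accompanying
prose (kappa haplotype B lacking the 36-gene distal cluster; beta haplotype B
deleting TRBV3-2/TRBV4-3/TRBV6-3 and the trypsinogen-like T7/T8; gamma
haplotype B deleting V4+V5 and haplotype C inserting V3P; lambda haplotypes
B–E carrying one to four extra J-C cassettes).  For the heavy-chain constant
CNV, haplotypes B–G are the six multigene deletions encoded as contiguous
absent blocks, with haplotype D spanning IGHA1..IGHE inclusive of IGHGP (the
individual lacking IgA1, IgG2, IgG4 and IgE); blocks not pinned by prose are
schematic, as is the whole B–F content of the heavy-chain V-region panel,
whose fixture is labelled `_synthetic` and used for invariant tests only.

## Locus units, IDs and coordinates

Locus IDs follow the 3+3(+3) taxon-abbreviation rule
(`Macmul_IGL_2`, `Canlupfam_TRB_1`); the 9-letter subspecies form is a
documented assumption (only its existence, not its formation, is specified).
Flat-file fragments use the EMBL feature-table layout — key at column 6,
location/qualifiers at column 22, wrap at 80 columns — since published
renderings do not preserve columns.  Qualifiers are emitted sorted byte-wise
by name, which reproduces the published order exactly and makes rendering
deterministic; the serializer emits straight ASCII quotes and the parser also
accepts typographic ones.  All ten qualifiers are mandatory for rendering;
parsing reports which are missing.  Construction enforces
`length == end − start + 1` and `complement == (orientation is REV)`.  A
locus with no usable flanking borne carries the sentinel `+10kb` (a minimal
10 kb margin beyond the outermost gene).  Borne values are checked against
the shipped borne table as warnings, not errors, since several loci have no
defined borne.

Coordinates are 1-based inclusive throughout (the convention of the
positions strings being modelled); no half-open interfaces are exposed.  FWD
mapping is `pos − start + 1`, REV mapping `end − pos + 1`; bijectivity is
verified exhaustively on frames up to 10⁴ positions.

## Synthetic generator

`generate_locus` emulates the structural features the real tables exhibit —
canonical V-D-J-C organization, functionality mix, clan-designated V
pseudogenes, interspersed RPI markers, dotted insertion orders, haplotype
indel blocks — from a single `random.Random` seeded by the config (no global
state; a fixed seed reproduces the table bit-for-bit).  Defaults: 40 V, 5 D,
6 J, 2 C genes; functionality weights F 0.35 / ORF 0.10 / P 0.55 (roughly
the heavy-chain V mix, where pseudogenes dominate); 5% marker intersperse
and dotted-insertion rates; 3 haplotypes with probability 0.5 of a deletion
block and of a dotted-order insertion each.  These were chosen once as a
realistic mid-size locus.

What the generator does *not* emulate: real subgroup phylogeny, sequence
content, biased spatial clustering of pseudogenes, linkage between CNVs, or
population frequencies.  Passing property tests therefore demonstrates
structural correctness of parsing/derivation/diffing, not fidelity to any
biological distribution.

## Problem sizes and numerics

Everything here is exact integer/string computation; there are no tolerances,
optimizers or floating-point comparisons.  Property tests run the published
tables exhaustively (≈ 700 rows), 1000 randomized symbol and definition
round-trips, 200 randomized flat-file records, 20 synthetic-locus oracle
comparisons and two exhaustive 10⁴-position coordinate frames; the suite
completes in a few seconds.  The statistical sanity check on the generator
uses 1200 genes and a 3σ binomial band per functionality code.

## Known limitations

- Allele-level data (`*01` suffixes), sequence alignment and any
  nucleotide-level processing are out of scope by design.
- The exchange status `e` carries no payload (which gene replaced which);
  the letter is all the nomenclature defines.
- The heavy-chain V-region haplotype panel content (B–F) is schematic; only
  its invariants are meaningful.
- Counts such as "54 alpha V genes" or "19 or 22 gamma genes per haploid
  genome" are not asserted anywhere: the published row inventories do not
  reduce to them arithmetically, and the fixtures store rows verbatim.
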