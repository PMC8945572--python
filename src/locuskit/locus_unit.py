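"""Locus-unit records: the flat-file description of a locus in an assembly.

A locus extracted from a genome assembly is described by a feature-table
fragment whose key is ``IMGT-LOCUS-UNIT`` and whose ten qualifiers give the
locus identity (ID, name, chromosome), extent (length, positions on the
chromosome sequence), orientation (forward FWD / reverse REV — a REV locus is
presented reverse-complemented in its own 5'->3' reference sequence) and
delimitation (most-5'/most-3' IG/TR gene, and the conserved non-IG/TR
flanking genes, the 5' and 3' *bornes*).

The dialect follows the EMBL feature-table layout: feature key at column 6,
location and qualifiers at column 22, lines wrapped at 80 columns.  The
serializer emits straight ASCII double quotes; the parser also accepts the
typographic quotes found in published renderings.
"""

from __future__ import annotations

import re
import textwrap
from dataclasses import dataclass

from .errors import FlatFileParseError, InputError, ValidationError
from .genes import BorneEntry

_KEY_COLUMN = 5  # 0-based; feature key starts at column 6
_QUAL_COLUMN = 21  # 0-based; location/qualifiers start at column 22
_WRAP = 80

#: sentinel borne for loci whose flanking gene is unknown or too distant:
#: a minimal 10 kb margin is added beyond the outermost IG/TR gene instead.
FALLBACK_BORNE = "+10kb"

_QUOTES = "\"“”’‘"


class LocusOrientation:
    FWD = "forward (FWD)"
    REV = "reverse (REV)"


@dataclass(frozen=True)
class AccessionId:
    """Sequence-database accession of a locus reference: IMGT + 6 digits."""

    value: str

    def __post_init__(self) -> None:
        if not re.fullmatch(r"IMGT\d{6}", self.value):
            raise ValidationError(
                f"accession must be 'IMGT' followed by 6 digits, got {self.value!r}"
            )

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class AssemblyRef:
    """Provenance of the genome assembly a locus was extracted from."""

    organism: str
    taxon_id: int
    isolate: str
    assembly_name: str
    genbank_assembly_id: str
    refseq_assembly_id: str
    common_name: str = ""
    assembly_uid: str = ""

    def __post_init__(self) -> None:
        if not self.assembly_name:
            raise ValidationError("assembly_name must be non-empty")


@dataclass(frozen=True)
class Positions:
    """Location of the locus on its chromosome sequence (1-based inclusive)."""

    accession: str
    start: int
    end: int
    complement: bool

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError("positions must satisfy 1 <= start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class LocusUnit:
    """The ten-qualifier locus-unit record."""

    locus_name: str  # "<Genus species> <LOCUS>"
    locus_id: str
    chromosome: str
    length_bp: int
    orientation: str  # LocusOrientation.FWD or LocusOrientation.REV
    positions: Positions
    five_prime_gene: str
    three_prime_gene: str
    five_prime_borne: str
    three_prime_borne: str

    def __post_init__(self) -> None:
        if self.orientation not in (LocusOrientation.FWD, LocusOrientation.REV):
            raise ValidationError(f"orientation must be FWD/REV form, got {self.orientation!r}")
        if self.length_bp != self.positions.length:
            raise ValidationError(
                f"length {self.length_bp} bp does not match positions span "
                f"{self.positions.length} bp"
            )
        if self.positions.complement != (self.orientation == LocusOrientation.REV):
            raise ValidationError("complement flag must mirror REV orientation")

    @property
    def span(self) -> tuple[int, int]:
        """Extent in the locus's own reference sequence: 1..length."""
        return (1, self.length_bp)

    def qualifiers(self) -> dict[str, str]:
        pos = self.positions
        comp = " complement" if pos.complement else ""
        return {
            "IMGT_locus_3prime_borne": self.three_prime_borne,
            "IMGT_locus_3prime_gene": self.three_prime_gene,
            "IMGT_locus_5prime_borne": self.five_prime_borne,
            "IMGT_locus_5prime_gene": self.five_prime_gene,
            "IMGT_locus_ID": self.locus_id,
            "IMGT_locus_chromosome": self.chromosome,
            "IMGT_locus_length": f"{self.length_bp} bp",
            "IMGT_locus_name": self.locus_name,
            "IMGT_locus_orientation": self.orientation,
            "IMGT_locus_positions": f"{pos.accession} ({pos.start}-{pos.end}{comp})",
        }

    def check_bornes(self, bornes: list[BorneEntry]) -> list[str]:
        """Compare the record's bornes against a reference borne table.

        Returns warning strings (not errors: several loci have no defined
        borne, marked "N.d." in the reference table).
        """
        locus = self.locus_name.split()[-1]
        warnings = []
        for side, value in (
            ("5prime", self.five_prime_borne),
            ("3prime", self.three_prime_borne),
        ):
            expected = [
                b.gene_name
                for b in bornes
                if b.side == side and locus in b.locus.split("/")
            ]
            if not expected:
                continue
            if value == FALLBACK_BORNE:
                continue
            if value not in expected and "N.d." not in expected and "N.d" not in expected:
                warnings.append(
                    f"{side} borne {value!r} not among reference bornes {expected} "
                    f"for locus {locus}"
                )
        return warnings


# ---------------------------------------------------------------------------
# Locus IDs


def make_locus_id(
    genus: str,
    species_epithet: str,
    locus: str,
    n: int,
    subspecies_epithet: str | None = None,
) -> str:
    """Build a locus ID: taxon abbreviation + locus type + chronological number.

    The abbreviation takes the capitalized first three letters of the genus
    and the lowercase first three of the species epithet (plus three of the
    subspecies epithet when given), e.g. ``Macmul_IGL_2``.
    """
    parts = [genus, species_epithet] + ([subspecies_epithet] if subspecies_epithet else [])
    for name in parts:
        if len(name) < 3 or not name.isalpha():
            raise InputError(f"name {name!r} must be alphabetic with at least 3 letters")
    if n < 1:
        raise InputError("chronological numbers start at 1")
    code = genus[:3].capitalize() + species_epithet[:3].lower()
    if subspecies_epithet:
        code += subspecies_epithet[:3].lower()
    return f"{code}_{locus}_{n}"


# ---------------------------------------------------------------------------
# Feature-table rendering / parsing


def _ft_line(content: str, at_key_column: bool = False) -> list[str]:
    indent = _KEY_COLUMN if at_key_column else _QUAL_COLUMN
    prefix = "FT" + " " * (indent - 2)
    width = _WRAP - _QUAL_COLUMN
    if len(prefix) + len(content) <= _WRAP:
        return [prefix + content]
    pieces = textwrap.wrap(content, width=width, break_long_words=False,
                           break_on_hyphens=False)
    cont = "FT" + " " * (_QUAL_COLUMN - 2)
    return [prefix + pieces[0]] + [cont + p for p in pieces[1:]]


def render_locus_unit(u: LocusUnit) -> list[str]:
    """Render the feature-table fragment.

    Qualifiers are emitted sorted byte-wise by name — a total, deterministic
    order (3prime_borne, 3prime_gene, 5prime_borne, 5prime_gene, ID,
    chromosome, length, name, orientation, positions).  Rendering the same
    record twice is byte-identical.
    """
    start, end = u.span
    lines = []
    key = "IMGT-LOCUS-UNIT"
    pad = " " * (_QUAL_COLUMN - _KEY_COLUMN - len(key))
    lines.append(f"FT   {key}{pad}{start}..{end}")
    for name in sorted(u.qualifiers()):
        value = u.qualifiers()[name]
        lines.extend(_ft_line(f'/{name}="{value}"'))
    return lines


_MANDATORY = (
    "IMGT_locus_3prime_borne",
    "IMGT_locus_3prime_gene",
    "IMGT_locus_5prime_borne",
    "IMGT_locus_5prime_gene",
    "IMGT_locus_ID",
    "IMGT_locus_chromosome",
    "IMGT_locus_length",
    "IMGT_locus_name",
    "IMGT_locus_orientation",
    "IMGT_locus_positions",
)

_POSITIONS_RE = re.compile(
    r"(?P<acc>\S+)\s*\((?P<start>\d+)-(?P<end>\d+)(?P<comp>,?\s*complement)?\)"
)


def parse_locus_unit(lines: list[str] | str) -> LocusUnit:
    """Parse a feature-table fragment back into a LocusUnit.

    Continuation lines are rejoined with a space; curly or straight quotes
    are accepted.  Missing mandatory qualifiers and length/positions
    mismatches are reported as errors.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    body: list[str] = []
    for line in lines:
        if not line.strip():
            continue
        if line.startswith("FT"):
            line = line[2:]
        body.append(line.strip())
    if not body:
        raise FlatFileParseError("empty locus-unit fragment")
    header = body[0]
    m = re.match(r"IMGT-LOCUS-UNIT\s+(\d+)\.\.(\d+)$", header)
    if not m:
        raise FlatFileParseError(f"bad feature header {header!r}")
    span = (int(m.group(1)), int(m.group(2)))

    # rejoin wrapped qualifier values
    chunks: list[str] = []
    for part in body[1:]:
        if part.startswith("/"):
            chunks.append(part)
        elif chunks:
            chunks[-1] += " " + part
        else:
            raise FlatFileParseError(f"continuation line before any qualifier: {part!r}")

    qualifiers: dict[str, str] = {}
    for chunk in chunks:
        qm = re.match(rf"/([A-Za-z0-9_]+)=([{_QUOTES}])(.*)([{_QUOTES}])$", chunk)
        if not qm:
            raise FlatFileParseError(f"bad qualifier line {chunk!r}")
        qualifiers[qm.group(1)] = qm.group(3)

    missing = [q for q in _MANDATORY if q not in qualifiers]
    if missing:
        raise FlatFileParseError(f"missing mandatory qualifiers: {', '.join(missing)}")

    lm = re.fullmatch(r"(\d+)\s*bp", qualifiers["IMGT_locus_length"])
    if not lm:
        raise FlatFileParseError(
            f"bad length value {qualifiers['IMGT_locus_length']!r}"
        )
    length = int(lm.group(1))
    pm = _POSITIONS_RE.fullmatch(qualifiers["IMGT_locus_positions"])
    if not pm:
        raise FlatFileParseError(
            f"bad positions value {qualifiers['IMGT_locus_positions']!r}"
        )
    positions = Positions(
        accession=pm.group("acc"),
        start=int(pm.group("start")),
        end=int(pm.group("end")),
        complement=bool(pm.group("comp")),
    )
    orientation = qualifiers["IMGT_locus_orientation"]
    unit = LocusUnit(
        locus_name=qualifiers["IMGT_locus_name"],
        locus_id=qualifiers["IMGT_locus_ID"],
        chromosome=qualifiers["IMGT_locus_chromosome"],
        length_bp=length,
        orientation=orientation,
        positions=positions,
        five_prime_gene=qualifiers["IMGT_locus_5prime_gene"],
        three_prime_gene=qualifiers["IMGT_locus_3prime_gene"],
        five_prime_borne=qualifiers["IMGT_locus_5prime_borne"],
        three_prime_borne=qualifiers["IMGT_locus_3prime_borne"],
    )
    if unit.span != span:
        raise FlatFileParseError(
            f"feature span {span} does not match length {length} bp"
        )
    return unit


# ---------------------------------------------------------------------------
# Definition (DE) lines


def render_definition_line(a: AssemblyRef, u: LocusUnit, acc: AccessionId) -> str:
    """Render the definition-line content of a locus reference accession.

    Comma-separated fields: organism (common name), taxon, isolate, assembly
    (with UID when known), assembly IDs, chromosome with positions, locus ID.
    """
    pos = u.positions
    comp = ", complement" if pos.complement else ""
    organism = a.organism + (f" ({a.common_name})" if a.common_name else "")
    fields = [
        organism,
        f"taxon:{a.taxon_id}",
        f"isolate: {a.isolate}",
        f"assembly {a.assembly_name}",
    ]
    if a.assembly_uid:
        fields.append(f"{a.assembly_uid} [UID]")
    fields += [
        f"GenBank assembly ID: {a.genbank_assembly_id}",
        f"Refseq assembly ID: {a.refseq_assembly_id}",
        f"chromosome {u.chromosome}: {pos.accession} ({pos.start}-{pos.end}{comp})",
        f"IMGT locus ID: {u.locus_id}",
    ]
    return f"{acc}; " + ", ".join(fields)


def parse_definition_line(text: str) -> dict[str, str]:
    """Split a rendered definition line back into its named fields."""
    acc, _, rest = text.partition("; ")
    if not re.fullmatch(r"IMGT\d{6}", acc):
        raise FlatFileParseError(f"bad accession prefix {acc!r}")
    out = {"accession": acc}
    m = re.match(r"([^,]+?)(?: \(([^)]*)\))?, taxon:(\d+), isolate: (.*?), assembly (\S+), "
                 r"(?:(\S+) \[UID\], )?GenBank assembly ID: (\S+), "
                 r"Refseq assembly ID: (\S+), chromosome (\S+): (\S+) "
                 r"\((\d+)-(\d+)(, complement)?\), IMGT locus ID: (\S+)$", rest)
    if not m:
        raise FlatFileParseError(f"malformed definition line {text!r}")
    (out["organism"], out["common_name"], out["taxon_id"], out["isolate"],
     out["assembly_name"], out["assembly_uid"], out["genbank_assembly_id"],
     out["refseq_assembly_id"], out["chromosome"], out["accession_chrom"],
     out["start"], out["end"], comp, out["locus_id"]) = m.groups()
    out["complement"] = "yes" if comp else "no"
    out["common_name"] = out["common_name"] or ""
    out["assembly_uid"] = out["assembly_uid"] or ""
    return out
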