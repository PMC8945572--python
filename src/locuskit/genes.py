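"""Gene nomenclature and locus gene-order tables for the IG and TR loci.

The seven antigen-receptor loci of higher vertebrates (IGH, IGK, IGL for the
immunoglobulins; TRA, TRB, TRG, TRD for the T cell receptors) are described by
ordered tables of V, D, J and C genes.  Each gene carries a standardized symbol
(``IGHV3-30-3``, ``TRBC1``, ``IGHV(III)-67-4D`` ...), a functionality call
(F, ORF, P, possibly dual), a relative position in the locus (the *gene
order*, with dotted decimals marking insertions against a reference ruler and
0 marking an unknown position) and an orientation of transcription relative to
the locus.  Non-IG/TR marker genes interspersed in a locus (golgin
pseudogenes, trypsinogen-like genes, ...) are kept as first-class *RPI*
records so that copy-number spans can count them.

This module provides the parsed forms of those four columns, a symbol grammar
with exact round-trip serialization, the ordered table container and its TSV
dialect, and counting utilities.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterator

from .errors import GeneNameParseError, InputError, MissingGeneError, ValidationError

LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRD", "TRG")
GENE_TYPES = ("V", "D", "J", "C")

#: designations of the heavy-chain constant (isotype) genes, printed without a
#: "C" type letter: IGHM, IGHD, IGHG3, IGHGP, IGHEP1, IGHA2 ...
_IGH_ISOTYPE = re.compile(r"M|D|E|EP1|GP|G\d+|A\d+")

_CLAN = re.compile(r"\(([IVX]+)\)")
_VD_TOKEN = re.compile(r"\d+[DP]?|NL\d+|[A-Z]")
_JC_TOKEN = re.compile(r"[A-Za-z0-9]+")


class Category(str, Enum):
    IG_TR = "IG_TR"
    RPI = "RPI"


class Orientation(str, Enum):
    DIRECT = "direct"
    OPPOSITE = "opposite"
    UNKNOWN = "N.d"

    @classmethod
    def parse(cls, text: str) -> "Orientation":
        t = text.strip().rstrip(".")
        for member in cls:
            if member.value.rstrip(".") == t:
                return member
        raise ValidationError(f"unknown orientation {text!r}")


# ---------------------------------------------------------------------------
# Functionality


@dataclass(frozen=True)
class Functionality:
    """Functionality annotation of a gene.

    ``codes`` is the ordered tuple of calls among F (functional), ORF (open
    reading frame) and P (pseudogene); a dual value such as ``F, ORF``
    reflects allele- or assembly-dependent status and is kept as one ordered
    pair, not two alternatives.  ``sentinel`` replaces the codes for genes
    whose functionality is not a regular call: ``N.d`` (not defined, IG/TR
    genes) or ``nr`` (nonrelevant, RPI genes).
    """

    codes: tuple[str, ...] = ()
    sentinel: str | None = None

    SENTINELS = ("N.d", "nr")

    def __post_init__(self) -> None:
        if self.sentinel is not None:
            if self.sentinel not in self.SENTINELS:
                raise ValidationError(f"unknown sentinel {self.sentinel!r}")
            if self.codes:
                raise ValidationError("sentinel functionality cannot carry F/ORF/P codes")
        else:
            if not self.codes:
                raise ValidationError("functionality needs at least one code")
            for c in self.codes:
                if c not in ("F", "ORF", "P"):
                    raise ValidationError(f"unknown functionality code {c!r}")

    @classmethod
    def parse(cls, text: str) -> "Functionality":
        t = text.strip()
        if t.rstrip(".") == "N.d".rstrip("."):
            return cls(sentinel="N.d")
        if t == "nr":
            return cls(sentinel="nr")
        codes = tuple(part.strip() for part in t.split(","))
        return cls(codes=codes)

    def __str__(self) -> str:
        if self.sentinel:
            return self.sentinel
        return ", ".join(self.codes)

    @property
    def code(self) -> str:
        """Compact one-or-two-letter code used in CNV definitions.

        Single calls map F -> "F", ORF -> "O", P -> "P"; dual calls
        concatenate in source order (F,ORF -> "FO"; ORF,P -> "OP").
        Sentinels map to themselves.
        """
        if self.sentinel:
            return self.sentinel
        return "".join("O" if c == "ORF" else c for c in self.codes)


def functionality_code(f: Functionality) -> str:
    return f.code


# ---------------------------------------------------------------------------
# Gene order


@dataclass(frozen=True, order=True)
class GeneOrder:
    """Relative 5'->3' position in a locus.

    ``major`` 0 means the position is unknown; a non-zero ``minor`` encodes a
    dotted insertion order such as 17.1, which sorts between 17 and 18.
    """

    major: int
    minor: int = 0

    def __post_init__(self) -> None:
        if self.major < 0 or self.minor < 0:
            raise ValidationError("gene order components must be non-negative")

    @classmethod
    def parse(cls, text: str) -> "GeneOrder":
        t = text.strip()
        if "." in t:
            major, minor = t.split(".", 1)
            return cls(int(major), int(minor))
        return cls(int(t))

    def __str__(self) -> str:
        if self.minor:
            return f"{self.major}.{self.minor}"
        return str(self.major)

    @property
    def known(self) -> bool:
        return self.major > 0


# ---------------------------------------------------------------------------
# Gene names


@dataclass(frozen=True)
class GeneName:
    """Parsed structure of an IG/TR gene symbol.

    IG/TR symbols decompose as locus code + gene type + optional clan (Roman
    numeral in parentheses) + hyphen-separated designation tokens.  The first
    token of a V gene is its subgroup number (possibly carrying the distal
    "D" marker, as in IGKV1D-8, or a provisional "P", as in TRGV3P) or a
    provisional capital letter (TRAVA); later tokens are localization numbers,
    the last optionally flagged "D" for a duplicated gene (IGHV1-69D).  The
    heavy-chain constant genes print their isotype directly after the locus
    (IGHM, IGHG3): ``implicit_type`` marks that the "C" type letter is not
    written.  Hybrid symbols such as TRAV14/DV4 carry the second designation
    as a nested ``hybrid`` name.  Symbols that match no IG/TR pattern are
    opaque RPI names kept verbatim in ``opaque``.
    """

    category: Category
    locus: str | None = None
    gene_type: str | None = None
    clan: str | None = None
    tokens: tuple[str, ...] = ()
    implicit_type: bool = False
    hybrid: "GeneName | None" = None
    opaque: str | None = None

    def __post_init__(self) -> None:
        if self.category is Category.RPI:
            if not self.opaque:
                raise ValidationError("RPI gene names keep the verbatim symbol")
        else:
            if self.locus not in LOCI:
                raise ValidationError(f"unknown locus {self.locus!r}")
            if self.gene_type not in GENE_TYPES:
                raise ValidationError(f"unknown gene type {self.gene_type!r}")
            if self.clan is not None and self.gene_type != "V":
                raise ValidationError("only V genes carry a clan")

    # -- derived views ------------------------------------------------

    @property
    def raw_symbol(self) -> str:
        return format_gene_name(self)

    @property
    def subgroup(self) -> str | None:
        """Numeric subgroup of a V/D gene (None for clan-designated genes)."""
        if self.category is Category.RPI or self.clan is not None:
            return None
        if self.gene_type in ("V", "D") and self.tokens:
            m = re.match(r"\d+", self.tokens[0])
            if m:
                return m.group(0)
        return None

    @property
    def localization(self) -> tuple[int, ...]:
        """Numeric localization components (e.g. (30, 3) for IGHV3-30-3)."""
        if self.category is Category.RPI:
            return ()
        toks = self.tokens if self.clan is not None else self.tokens[1:]
        out = []
        for t in toks:
            m = re.match(r"\d+", t)
            if m and not t.startswith("NL"):
                out.append(int(m.group(0)))
        return tuple(out)

    @property
    def duplicate_flag(self) -> bool:
        """True when any designation token carries the duplicate "D" marker."""
        return any(re.fullmatch(r"\d+D", t) for t in self.tokens)

    @property
    def not_localized(self) -> bool:
        return any(t.startswith("NL") for t in self.tokens)

    def __str__(self) -> str:
        return self.raw_symbol


def _parse_body(locus: str, gene_type: str, body: str, symbol: str) -> GeneName:
    clan = None
    m = _CLAN.match(body)
    if m:
        clan = m.group(1)
        body = body[m.end():]
        if body and not body.startswith("-"):
            raise GeneNameParseError(f"clan must be followed by a hyphen in {symbol!r}")
        body = body.lstrip("-")
    hybrid = None
    if "/" in body:
        body, hyb = body.split("/", 1)
        # e.g. "DV4": first letter selects the nested locus, second the type
        if len(hyb) < 3 or hyb[1] not in GENE_TYPES:
            raise GeneNameParseError(f"malformed hybrid designation in {symbol!r}")
        hyb_locus = locus[:2] + hyb[0]
        if hyb_locus not in LOCI:
            raise GeneNameParseError(f"unknown hybrid locus in {symbol!r}")
        hybrid = _parse_body(hyb_locus, hyb[1], hyb[2:], symbol)
    tokens = tuple(body.split("-")) if body else ()
    token_re = _VD_TOKEN if gene_type in ("V", "D") else _JC_TOKEN
    for t in tokens:
        if not token_re.fullmatch(t):
            raise GeneNameParseError(f"bad designation token {t!r} in {symbol!r}")
    if clan is None and gene_type in ("V", "D") and not tokens:
        raise GeneNameParseError(f"{symbol!r} lacks a designation")
    return GeneName(
        category=Category.IG_TR,
        locus=locus,
        gene_type=gene_type,
        clan=clan,
        tokens=tokens,
        hybrid=hybrid,
    )


def parse_gene_name(symbol: str) -> GeneName:
    """Parse a gene symbol; unmatched symbols come back as opaque RPI names.

    >>> parse_gene_name("IGHV3-30-3").localization
    (30, 3)
    >>> parse_gene_name("GOLGA4P1").category
    <Category.RPI: 'RPI'>
    """
    if not symbol or not symbol.strip():
        raise InputError("empty gene symbol")
    s = symbol.strip()
    locus = s[:3]
    if locus in LOCI and len(s) > 3:
        rest = s[3:]
        if locus == "IGH" and _IGH_ISOTYPE.fullmatch(rest):
            return GeneName(
                category=Category.IG_TR,
                locus=locus,
                gene_type="C",
                tokens=(rest,),
                implicit_type=True,
            )
        if rest[0] in GENE_TYPES:
            try:
                return _parse_body(locus, rest[0], rest[1:], s)
            except GeneNameParseError:
                pass
    return GeneName(category=Category.RPI, opaque=s)


def format_gene_name(g: GeneName) -> str:
    """Serialize a GeneName; inverse of :func:`parse_gene_name`."""
    if g.category is Category.RPI:
        return g.opaque or ""
    parts = [g.locus]
    if not g.implicit_type:
        parts.append(g.gene_type)
    if g.clan is not None:
        parts.append(f"({g.clan})")
        if g.tokens:
            parts.append("-" + "-".join(g.tokens))
    elif g.tokens:
        parts.append("-".join(g.tokens))
    if g.hybrid is not None:
        h = g.hybrid
        hyb_tokens = "-".join(h.tokens)
        parts.append(f"/{h.locus[2]}{h.gene_type}{hyb_tokens}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Records and tables


@dataclass(frozen=True)
class GeneRecord:
    """One row of a locus gene-order table."""

    name: GeneName
    functionality: Functionality
    order: GeneOrder
    orientation: Orientation
    cnv_role: str | None = None

    def __post_init__(self) -> None:
        if self.orientation is Orientation.UNKNOWN and self.order.known:
            raise ValidationError(
                f"{self.name}: orientation N.d is only allowed at unknown position"
            )


@dataclass
class GeneOrderTable:
    """Ordered collection of gene records for one locus of one species."""

    species: str
    locus: str
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[GeneOrder, GeneRecord] = {}
        for rec in self.records:
            if not rec.order.known:
                continue
            if rec.order in seen:
                raise ValidationError(
                    f"duplicate gene order {rec.order}: "
                    f"{seen[rec.order].name} and {rec.name}"
                )
            seen[rec.order] = rec

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sorted_records(self) -> list[GeneRecord]:
        """Records with known position, sorted by gene order."""
        return sorted((r for r in self.records if r.order.known), key=lambda r: r.order)

    def find(self, symbol: str) -> GeneRecord:
        for rec in self.records:
            if rec.name.raw_symbol == symbol:
                return rec
        raise MissingGeneError(f"gene {symbol!r} not in {self.locus} table")

    def __contains__(self, symbol: str) -> bool:
        return any(rec.name.raw_symbol == symbol for rec in self.records)


Predicate = Callable[[GeneRecord], bool]


def count_genes(
    table: GeneOrderTable,
    predicate: Predicate | None = None,
    *,
    include_unpositioned: bool = False,
) -> int:
    """Count records matching ``predicate``.

    Genes at order 0 (position unknown) are excluded from all counts unless
    ``include_unpositioned`` explicitly selects them.
    """
    n = 0
    for rec in table:
        if not rec.order.known and not include_unpositioned:
            continue
        if predicate is None or predicate(rec):
            n += 1
    return n


def gene_filter(
    *,
    gene_type: str | None = None,
    locus: str | None = None,
    category: Category | None = None,
    functionality: str | None = None,
) -> Predicate:
    """Build a record predicate from common field selections.

    ``functionality`` matches the compact code ("F", "OP", "nr", ...).
    """

    def pred(rec: GeneRecord) -> bool:
        if gene_type is not None and rec.name.gene_type != gene_type:
            return False
        if locus is not None and rec.name.locus != locus:
            return False
        if category is not None and rec.name.category is not category:
            return False
        if functionality is not None and rec.functionality.code != functionality:
            return False
        return True

    return pred


# ---------------------------------------------------------------------------
# Bornes (locus-flanking conserved genes)


@dataclass(frozen=True)
class BorneEntry:
    """A conserved non-IG/TR gene flanking a locus at its 5' or 3' end."""

    locus: str
    side: str  # "5prime" or "3prime"
    gene_name: str  # symbol or "N.d."
    gene_description: str = ""
    occurrence: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("5prime", "3prime"):
            raise ValidationError(f"borne side must be 5prime/3prime, got {self.side!r}")


# ---------------------------------------------------------------------------
# TSV dialect

_FIXED_COLUMNS = ("gene_name", "functionality", "order", "orientation")


@dataclass
class RawTable:
    """Low-level parsed TSV: metadata, header and row dictionaries."""

    species: str
    locus: str
    columns: list[str]
    rows: list[dict[str, str]]

    @property
    def haplotype_columns(self) -> list[str]:
        fixed = set(_FIXED_COLUMNS) | {"cnv_role"}
        return [c for c in self.columns if c not in fixed]


def read_table(path: str | Path) -> RawTable:
    """Read the gene-order TSV dialect (comment metadata + header + rows)."""
    meta: dict[str, str] = {}
    lines: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta.setdefault(key.strip(), value.strip())
                continue
            if line.strip():
                lines.append(line)
    if not lines:
        raise ValidationError(f"{path}: no header row")
    reader = csv.reader(lines, delimiter="\t")
    columns = next(reader)
    rows = []
    for values in reader:
        values += [""] * (len(columns) - len(values))
        rows.append(dict(zip(columns, values)))
    return RawTable(
        species=meta.get("species", ""),
        locus=meta.get("locus", ""),
        columns=columns,
        rows=rows,
    )


def _record_from_row(row: dict[str, str], path: str | Path) -> GeneRecord:
    try:
        return GeneRecord(
            name=parse_gene_name(row["gene_name"]),
            functionality=Functionality.parse(row["functionality"]),
            order=GeneOrder.parse(row["order"]),
            orientation=Orientation.parse(row["orientation"]),
            cnv_role=row.get("cnv_role", "").strip() or None,
        )
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"{path}: bad row {row.get('gene_name')!r}: {exc}") from exc


def load_gene_order(path: str | Path) -> GeneOrderTable:
    """Load a gene-order table from its TSV dialect."""
    raw = read_table(path)
    records = [_record_from_row(row, path) for row in raw.rows]
    return GeneOrderTable(species=raw.species, locus=raw.locus, records=records)


def save_gene_order(table: GeneOrderTable, path: str | Path) -> None:
    """Write a gene-order table; load(save(t)) == t, rows kept in order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# species: {table.species}\n")
        fh.write(f"# locus: {table.locus}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_FIXED_COLUMNS + ("cnv_role",))
        for rec in table:
            writer.writerow(
                [
                    rec.name.raw_symbol,
                    str(rec.functionality),
                    str(rec.order),
                    rec.orientation.value,
                    rec.cnv_role or "",
                ]
            )


def load_bornes(path: str | Path) -> list[BorneEntry]:
    """Load the locus 5'/3' borne table."""
    raw = read_table(path)
    return [
        BorneEntry(
            locus=row["locus"],
            side=row["side"],
            gene_name=row["gene_name"],
            gene_description=row.get("gene_description", ""),
            occurrence=row.get("occurrence", ""),
        )
        for row in raw.rows
    ]
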