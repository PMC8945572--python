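"""Standardized copy-number-variation (CNV) definitions.

A CNV names a locus segment whose gene content varies between haplotypes.  It
is delimited by a 5prime gene and a 3prime gene, and summarized by a
definition string of the form ``<group>(<start>-<end>)<total>(<counts>)``:
the group label, the gene orders of the first and last member (the genes
following the 5prime and preceding the 3prime delimiter), the total number of
genes in the span (IG/TR and interspersed RPI alike) and a tally of members
per compact functionality code, e.g. ``IGHV(17-20)7(3F,4P)``.  Spans whose
members are all RPI collapse the tally to the sentinel ``nr``; spans whose
IG/TR members are all of undetermined functionality collapse to ``N.d``.

CNVs are identified as ``<Genus species> <LOCUS> CNV<n>``, optionally suffixed
with a status letter: ``i`` insertion, ``d`` deletion, ``e`` exchange.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .errors import CnvParseError, InputError, MissingGeneError, ValidationError
from .genes import (
    Category,
    GeneName,
    GeneOrder,
    GeneOrderTable,
    GeneRecord,
    parse_gene_name,
)

#: canonical rendering order of the tally codes
COUNT_ORDER = ("F", "O", "P", "FO", "FP", "OP", "RPI", "N.d")

_STATUS_LETTERS = ("i", "d", "e")


@dataclass(frozen=True)
class CnvStatus:
    """Status of a gene in a haplotype: i(nsertion), d(eletion), e(xchange)."""

    letter: str

    def __post_init__(self) -> None:
        if self.letter not in _STATUS_LETTERS:
            raise ValidationError(f"CNV status letter must be one of {_STATUS_LETTERS}")

    def __str__(self) -> str:
        return self.letter


@dataclass(frozen=True)
class CnvBoundary:
    """5prime/3prime delimiter genes of a CNV.

    ``three_prime`` may be None when no 3prime delimiter is defined (the
    heavy-chain constant CNV has none); the span end is then given explicitly
    to :func:`derive_cnv_definition`.
    """

    five_prime: GeneName
    three_prime: GeneName | None = None

    @classmethod
    def of(cls, five_prime: str, three_prime: str | None = None) -> "CnvBoundary":
        return cls(
            parse_gene_name(five_prime),
            parse_gene_name(three_prime) if three_prime else None,
        )


@dataclass
class CnvDefinition:
    """Structured form of a standardized CNV definition.

    ``counts`` maps compact functionality codes to member counts; it is None
    when the whole tally collapses to ``sentinel`` ("nr" or "N.d").  The
    structured span keeps exact (possibly dotted) gene orders even where the
    rendered string truncates them.
    """

    group_label: str
    start_order: GeneOrder
    end_order: GeneOrder
    total: int
    counts: dict[str, int] | None = None
    sentinel: str | None = None
    species: str | None = None
    locus: str | None = None
    cnv_number: int | None = None

    def __post_init__(self) -> None:
        if (self.counts is None) == (self.sentinel is None):
            raise ValidationError("exactly one of counts/sentinel must be set")
        if self.sentinel is not None and self.sentinel not in ("nr", "N.d"):
            raise ValidationError(f"unknown sentinel {self.sentinel!r}")
        if self.counts is not None:
            bad = set(self.counts) - set(COUNT_ORDER)
            if bad:
                raise ValidationError(f"unknown count codes {sorted(bad)}")
            if sum(self.counts.values()) != self.total:
                raise ValidationError(
                    f"counts sum {sum(self.counts.values())} != total {self.total}"
                )
        if self.start_order > self.end_order:
            raise ValidationError("start order must not exceed end order")

    def core(self) -> tuple:
        """Span/tally content, ignoring provenance (species, locus, number)."""
        counts = dict(sorted(self.counts.items())) if self.counts else None
        return (self.group_label, self.start_order, self.end_order, self.total,
                counts, self.sentinel)


# ---------------------------------------------------------------------------
# Derivation from a gene-order table


def _auto_group_label(members: list[GeneRecord], table: GeneOrderTable) -> str:
    igtr = [m for m in members if m.name.category is Category.IG_TR]
    if not igtr:
        return f"{members[0].name.raw_symbol}-{members[-1].name.raw_symbol}"
    loci = {m.name.locus for m in igtr}
    types = {m.name.gene_type for m in igtr}
    if len(loci) == 1:
        locus = loci.pop()
        if len(types) == 1:
            return f"{locus}{types.pop()}"
        if types == {"J", "C"}:
            return f"{locus}J-{locus}C"
    return f"{members[0].name.raw_symbol}-{members[-1].name.raw_symbol}"


def derive_cnv_definition(
    table: GeneOrderTable,
    boundary: CnvBoundary,
    group_label: str | None = None,
    *,
    end_order: GeneOrder | None = None,
    species: str | None = None,
    number: int | None = None,
) -> CnvDefinition:
    """Derive the standardized definition of the span between two delimiters.

    Members are all records (IG/TR and RPI alike) with an order strictly
    between the delimiters; genes at unknown position never participate.
    When ``boundary.three_prime`` is None, ``end_order`` bounds the span
    inclusively.
    """
    five = table.find(boundary.five_prime.raw_symbol)
    if boundary.three_prime is not None:
        three = table.find(boundary.three_prime.raw_symbol)
        hi = three.order
        if five.order >= hi:
            raise ValidationError("5prime delimiter must precede 3prime delimiter")
        members = [
            r for r in table.sorted_records() if five.order < r.order < hi
        ]
    else:
        if end_order is None:
            raise InputError("an explicit end_order is required without a 3prime delimiter")
        members = [
            r for r in table.sorted_records() if five.order < r.order <= end_order
        ]
    if not members:
        raise ValidationError("empty CNV span")
    return _definition_from_members(members, table, group_label, species, number)


def _definition_from_members(
    members: list[GeneRecord],
    table: GeneOrderTable,
    group_label: str | None,
    species: str | None,
    number: int | None,
) -> CnvDefinition:
    tally: Counter[str] = Counter()
    for m in members:
        if m.name.category is Category.RPI:
            tally["RPI"] += 1
        else:
            tally[m.functionality.code] += 1

    igtr_codes = set(tally) - {"RPI"}
    counts: dict[str, int] | None
    sentinel: str | None
    if set(tally) == {"RPI"}:
        counts, sentinel = None, "nr"
    elif igtr_codes == {"N.d"}:
        counts, sentinel = None, "N.d"
    else:
        counts, sentinel = dict(tally), None

    return CnvDefinition(
        group_label=group_label or _auto_group_label(members, table),
        start_order=members[0].order,
        end_order=members[-1].order,
        total=len(members),
        counts=counts,
        sentinel=sentinel,
        species=species or table.species or None,
        locus=table.locus or None,
        cnv_number=number,
    )


def derive_cnv_span(
    table: GeneOrderTable,
    start_order: GeneOrder,
    end_order: GeneOrder,
    group_label: str | None = None,
    *,
    species: str | None = None,
    number: int | None = None,
) -> CnvDefinition:
    """Derive a definition over an explicit inclusive order span.

    Used where a CNV has no delimiter gene on one or both sides (a span at
    the very 5' end of a locus, or a constant-gene CNV without a 3' borne).
    """
    members = [
        r for r in table.sorted_records() if start_order <= r.order <= end_order
    ]
    if not members:
        raise ValidationError("empty CNV span")
    return _definition_from_members(members, table, group_label, species, number)


def derive_annotated_cnvs(table: GeneOrderTable) -> dict[int, tuple[CnvDefinition, str]]:
    """Derive every CNV annotated in the table's ``cnv_role`` column.

    Delimiters are rows marked ``CNV<n>-5prime`` / ``CNV<n>-3prime``; the row
    carrying ``CNV<n>=<definition>`` stores the expected rendering.  Returns
    ``{n: (derived definition, annotated string)}``.
    """
    five: dict[int, GeneRecord] = {}
    three: dict[int, GeneRecord] = {}
    members: dict[int, list[GeneRecord]] = {}
    annotated: dict[int, str] = {}
    for rec in table:
        role = rec.cnv_role
        if not role:
            continue
        for part in role.split(";"):
            m = re.fullmatch(r"CNV(\d+)-5prime", part)
            if m:
                five[int(m.group(1))] = rec
                continue
            m = re.fullmatch(r"CNV(\d+)-3prime", part)
            if m:
                three[int(m.group(1))] = rec
                continue
            m = re.fullmatch(r"CNV(\d+)(?:=(.*))?", part)
            if m:
                n = int(m.group(1))
                members.setdefault(n, []).append(rec)
                if m.group(2):
                    annotated[n] = m.group(2)

    out: dict[int, tuple[CnvDefinition, str]] = {}
    for n in sorted(set(five) | set(members)):
        if n in five:
            boundary = CnvBoundary(
                five[n].name, three[n].name if n in three else None
            )
            end = None
            if n not in three:
                end = max(r.order for r in members[n])
            d = derive_cnv_definition(table, boundary, end_order=end, number=n)
        else:
            # no delimiter marked (span at the 5' end of the locus)
            d = derive_cnv_span(
                table,
                min(r.order for r in members[n]),
                max(r.order for r in members[n]),
                number=n,
            )
        out[n] = (d, annotated.get(n, ""))
    return out


# ---------------------------------------------------------------------------
# Formatting and parsing


def _render_span(d: CnvDefinition) -> str:
    start, end = d.start_order, d.end_order
    # insertions between two integer orders render as that integer bracket
    s = str(start) if start.minor == 0 else str(start.major)
    e = str(end) if end.minor == 0 else str(end.major + 1)
    if s == e:
        return s
    return f"{s}-{e}"


def format_cnv_definition(d: CnvDefinition) -> str:
    """Render ``<group>(<span>)<total>(<counts>)``.

    Counts render in the canonical order F, O, P, FO, FP, OP, RPI; sentinels
    render bare.  A single-gene span renders one order only.  Dotted span
    bounds are truncated to the enclosing integer bracket (the published form
    for cassette insertions); the structured span is not altered.
    """
    if d.sentinel is not None:
        tally = d.sentinel
    else:
        tally = ",".join(
            f"{d.counts[code]}{code}" for code in COUNT_ORDER if d.counts.get(code)
        )
    return f"{d.group_label}({_render_span(d)}){d.total}({tally})"


_DEF_RE = re.compile(
    r"(?P<group>[^()\s]+)"
    r"\((?P<start>\d+(?:\.\d+)?)(?:-(?P<end>\d+(?:\.\d+)?))?\)"
    r"(?P<total>\d+)"
    r"\((?P<tally>[^()]*)\)"
    r"$"
)

_COUNT_RE = re.compile(r"(\d+)\s*(FO|FP|OP|RPI|N\.d|F|O|P)")


def parse_cnv_definition(s: str) -> CnvDefinition:
    """Parse a definition string back into its structured form.

    The parser tolerates stray spaces inside the counts list; the serializer
    never emits them.  A tally whose counts do not sum to the printed total
    is rejected.
    """
    if not s or not s.strip():
        raise CnvParseError("empty CNV definition")
    text = s.strip()
    m = _DEF_RE.match(text)
    if not m:
        # locate first offending character for the error position
        paren = text.find("(")
        raise CnvParseError(
            f"malformed CNV definition {text!r}",
            position=paren if paren >= 0 else 0,
        )
    group = m.group("group")
    start = GeneOrder.parse(m.group("start"))
    end = GeneOrder.parse(m.group("end")) if m.group("end") else start
    total = int(m.group("total"))
    tally = m.group("tally").strip()

    counts: dict[str, int] | None = None
    sentinel: str | None = None
    if tally in ("nr", "N.d", "N.d."):
        sentinel = "nr" if tally == "nr" else "N.d"
    else:
        counts = {}
        pos = m.start("tally")
        remaining = tally
        while remaining:
            cm = _COUNT_RE.match(remaining)
            if not cm:
                raise CnvParseError(
                    f"malformed count item in {text!r}", position=pos
                )
            code = cm.group(2)
            counts[code] = counts.get(code, 0) + int(cm.group(1))
            remaining = remaining[cm.end():].lstrip()
            if remaining.startswith(","):
                remaining = remaining[1:].lstrip()
        if sum(counts.values()) != total:
            raise CnvParseError(
                f"counts sum {sum(counts.values())} != total {total} in {text!r}",
                position=m.start("total"),
            )
    try:
        return CnvDefinition(
            group_label=group,
            start_order=start,
            end_order=end,
            total=total,
            counts=counts,
            sentinel=sentinel,
        )
    except ValidationError as exc:
        raise CnvParseError(str(exc)) from exc


def cnv_strings_equivalent(a: str, b: str) -> bool:
    """Order-insensitive comparison of two definition strings.

    The published tallies are not consistently ordered ("7F,1OP,1P" vs
    canonical "7F,1P,1OP"); comparison is on the parsed structures, whose
    count mapping ignores rendering order.
    """
    da, db = parse_cnv_definition(a), parse_cnv_definition(b)
    return da.core() == db.core()


def cnv_id(species: str, locus: str, n: int, status: CnvStatus | None = None) -> str:
    """Full CNV identifier, e.g. ``Homo sapiens IGH CNV1`` (or ``CNV1i``)."""
    if n < 1:
        raise InputError("CNV numbers start at 1")
    suffix = status.letter if status is not None else ""
    return f"{species} {locus} CNV{n}{suffix}"
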