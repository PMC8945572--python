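"""Seeded synthetic-locus generator and fixture validation.

The generator emulates the structure of real locus gene-order tables for
property testing: a block of V genes (with configurable functionality mix,
occasional clan-designated pseudogenes, interspersed non-IG/TR marker genes
and dotted insertion orders), followed by D, J and C blocks in the canonical
V-D-J-C organization, plus a haplotype table in which haplotype A is the
full main line and other haplotypes carry random contiguous deletion blocks
and insertions at dotted orders.

All randomness flows from a single ``random.Random`` seeded from the config;
there is no hidden global state, so a fixed seed reproduces the same locus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .cnv import parse_cnv_definition, derive_annotated_cnvs, CnvParseError
from .errors import LocusKitError, ValidationError
from .genes import (
    Category,
    Functionality,
    GeneName,
    GeneOrder,
    GeneOrderTable,
    GeneRecord,
    Orientation,
    parse_gene_name,
    read_table,
)
from .haplotypes import HaplotypeRow, HaplotypeTable, Presence

_ROMANS = ("I", "II", "III", "IV", "V", "VI", "VII")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic locus.

    Defaults are sized like a mid-scale V locus: 40 V genes with roughly the
    functionality mix of the heavy-chain table (about a third functional,
    half pseudogenes), five D, six J and two C genes, sparse marker-gene
    intersperse and occasional dotted insertions, three haplotypes with a
    one-in-two chance of an indel block each.
    """

    seed: int = 0
    locus: str = "IGH"
    n_v: int = 40
    n_d: int = 5
    n_j: int = 6
    n_c: int = 2
    functionality_weights: dict[str, float] = field(
        default_factory=lambda: {"F": 0.35, "ORF": 0.10, "P": 0.55}
    )
    p_rpi_intersperse: float = 0.05
    p_dotted_insertion: float = 0.05
    p_clan: float = 0.15
    n_haplotypes: int = 3
    p_deletion_block: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_rpi_intersperse", "p_dotted_insertion", "p_clan",
                     "p_deletion_block"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        total = sum(self.functionality_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"functionality_weights must sum to 1, got {total}")
        for n in (self.n_v, self.n_d, self.n_j, self.n_c, self.n_haplotypes):
            if n < 0:
                raise ValidationError("counts must be non-negative")


def _draw_functionality(rng: random.Random, weights: dict[str, float]) -> Functionality:
    codes, probs = zip(*weights.items())
    pick = rng.choices(codes, weights=probs)[0]
    expansion = {"F": ("F",), "O": ("ORF",), "P": ("P",), "FO": ("F", "ORF"),
                 "FP": ("F", "P"), "OP": ("ORF", "P")}
    return Functionality(codes=expansion.get(pick, (pick,)))


def generate_locus(cfg: GeneratorConfig) -> tuple[GeneOrderTable, HaplotypeTable]:
    """Generate a synthetic gene-order table and matching haplotype table.

    Deterministic for a fixed config; haplotype A carries the full main line.
    """
    rng = random.Random(cfg.seed)
    locus = cfg.locus
    records: list[GeneRecord] = []
    order = 0
    loc_counter = cfg.n_v  # localization numbers run 3'->5', so descend
    rpi_counter = 0

    def rpi_record(n: int) -> GeneRecord:
        nonlocal order
        order += 1
        return GeneRecord(
            name=GeneName(category=Category.RPI, opaque=f"RPIG{n}"),
            functionality=Functionality(sentinel="nr"),
            order=GeneOrder(order),
            orientation=rng.choice((Orientation.DIRECT, Orientation.OPPOSITE)),
        )

    # V block, with interspersed markers and dotted insertion orders
    for _ in range(cfg.n_v):
        if rng.random() < cfg.p_rpi_intersperse:
            rpi_counter += 1
            records.append(rpi_record(rpi_counter))
        order += 1
        if rng.random() < cfg.p_clan:
            name = GeneName(category=Category.IG_TR, locus=locus, gene_type="V",
                            clan=rng.choice(_ROMANS), tokens=(str(loc_counter),))
        else:
            name = GeneName(category=Category.IG_TR, locus=locus, gene_type="V",
                            tokens=(str(rng.randint(1, 7)), str(loc_counter)))
        records.append(GeneRecord(
            name=name,
            functionality=_draw_functionality(rng, cfg.functionality_weights),
            order=GeneOrder(order),
            orientation=Orientation.DIRECT,
        ))
        if rng.random() < cfg.p_dotted_insertion:
            # insertion against the ruler: dotted order, derived gene name
            records.append(GeneRecord(
                name=GeneName(category=Category.IG_TR, locus=locus, gene_type="V",
                              tokens=(str(rng.randint(1, 7)), str(loc_counter), "1")),
                functionality=_draw_functionality(rng, cfg.functionality_weights),
                order=GeneOrder(order, 1),
                orientation=Orientation.DIRECT,
            ))
        loc_counter -= 1

    def block(gene_type: str, count: int, namer) -> None:
        nonlocal order
        for i in range(1, count + 1):
            order += 1
            records.append(GeneRecord(
                name=namer(i),
                functionality=_draw_functionality(rng, cfg.functionality_weights),
                order=GeneOrder(order),
                orientation=Orientation.DIRECT,
            ))

    block("D", cfg.n_d, lambda i: GeneName(
        category=Category.IG_TR, locus=locus, gene_type="D",
        tokens=(str(rng.randint(1, 7)), str(i))))
    block("J", cfg.n_j, lambda i: GeneName(
        category=Category.IG_TR, locus=locus, gene_type="J", tokens=(str(i),)))
    if locus == "IGH":
        c_namer = lambda i: GeneName(category=Category.IG_TR, locus=locus,
                                     gene_type="C", tokens=(f"G{i}",),
                                     implicit_type=True)
    else:
        c_namer = lambda i: GeneName(category=Category.IG_TR, locus=locus,
                                     gene_type="C", tokens=(str(i),))
    block("C", cfg.n_c, c_namer)

    table = GeneOrderTable(species="Synthetica exempli", locus=locus,
                           records=records)

    # haplotypes: A is the full main line
    labels = [chr(ord("A") + i) for i in range(max(cfg.n_haplotypes, 1))]
    presence: dict[str, dict[str, Presence]] = {
        r.name.raw_symbol: {h: Presence.PRESENT for h in labels} for r in records
    }
    hap_rows_extra: list[GeneRecord] = []
    used_orders = {(r.order.major, r.order.minor) for r in records}
    for h in labels[1:]:
        if rng.random() < cfg.p_deletion_block and len(records) > 2:
            i = rng.randrange(len(records) - 1)
            j = min(len(records), i + rng.randint(1, 4))
            for rec in records[i:j]:
                presence[rec.name.raw_symbol][h] = Presence.ABSENT
        if rng.random() < cfg.p_deletion_block:
            # insertion at a dotted order: a gene absent in A, carried by h
            host = rng.choice([r for r in records if r.order.known])
            minor = host.order.minor + 5 + rng.randint(0, 3)
            name = GeneName(category=Category.IG_TR, locus=locus, gene_type="V",
                            tokens=(str(rng.randint(1, 7)),
                                    str(host.order.major), str(90 + minor)))
            sym = name.raw_symbol
            if sym in presence or (host.order.major, minor) in used_orders:
                continue
            used_orders.add((host.order.major, minor))
            rec = GeneRecord(
                name=name,
                functionality=_draw_functionality(rng, cfg.functionality_weights),
                order=GeneOrder(host.order.major, minor),
                orientation=Orientation.DIRECT,
            )
            hap_rows_extra.append(rec)
            presence[sym] = {lab: Presence.ABSENT for lab in labels}
            presence[sym][h] = Presence.INSERTED

    all_rows = records + hap_rows_extra
    table = GeneOrderTable(species=table.species, locus=locus, records=all_rows)
    hap = HaplotypeTable(
        haplotype_ids=labels,
        rows=[HaplotypeRow(gene=r, presence=presence[r.name.raw_symbol])
              for r in all_rows],
    )
    return table, hap


# ---------------------------------------------------------------------------
# Fixture validation


@dataclass
class FixtureReport:
    path: str
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return f"{self.path}: OK"
        return f"{self.path}: {len(self.issues)} issue(s)\n" + "\n".join(
            f"  - {i}" for i in self.issues
        )


def validate_fixture(path: str | Path) -> FixtureReport:
    """Check a gene-order fixture TSV for invariant violations.

    Reports: unparseable rows, symbols that fail the round-trip, unknown
    functionality strings, duplicate non-zero orders, orientation/order
    inconsistencies, malformed haplotype presence values, insertion rows not
    absent in haplotype A, and annotated CNV definitions that do not match
    what the delimiters derive.
    """
    report = FixtureReport(path=str(path))
    try:
        raw = read_table(path)
    except (OSError, LocusKitError) as exc:
        report.issues.append(f"unreadable: {exc}")
        return report

    seen_orders: dict[str, str] = {}
    records: list[GeneRecord] = []
    for row in raw.rows:
        sym = row.get("gene_name", "")
        try:
            name = parse_gene_name(sym)
            if name.raw_symbol != sym:
                report.issues.append(f"{sym}: does not round-trip ({name.raw_symbol})")
            functionality = Functionality.parse(row["functionality"])
            order = GeneOrder.parse(row["order"])
            orientation = Orientation.parse(row["orientation"])
            rec = GeneRecord(name=name, functionality=functionality, order=order,
                             orientation=orientation,
                             cnv_role=row.get("cnv_role", "").strip() or None)
            records.append(rec)
        except (LocusKitError, KeyError, ValueError) as exc:
            report.issues.append(f"{sym or '<row>'}: {exc}")
            continue
        if order.known:
            key = str(order)
            if key in seen_orders:
                report.issues.append(
                    f"duplicate order {key}: {seen_orders[key]} and {sym}"
                )
            else:
                seen_orders[key] = sym

    hap_labels = raw.haplotype_columns
    if hap_labels:
        if "A" not in hap_labels:
            report.issues.append("haplotype columns lack the reference haplotype A")
        for row in raw.rows:
            values = {}
            for label in hap_labels:
                v = row.get(label, "").strip().lower()
                try:
                    values[label] = Presence(v)
                except ValueError:
                    report.issues.append(
                        f"{row.get('gene_name')}: bad presence value {v!r} ({label})"
                    )
            a = values.get("A")
            for label, v in values.items():
                if v is Presence.INSERTED and a is not Presence.ABSENT:
                    report.issues.append(
                        f"{row.get('gene_name')}: inserted in {label} but not absent in A"
                    )

    if not report.issues:
        try:
            table = GeneOrderTable(species=raw.species, locus=raw.locus,
                                   records=records)
            from .cnv import format_cnv_definition, cnv_strings_equivalent

            for n, (derived, annotated) in derive_annotated_cnvs(table).items():
                if annotated and not cnv_strings_equivalent(
                    format_cnv_definition(derived), annotated
                ):
                    report.issues.append(
                        f"CNV{n}: derived {format_cnv_definition(derived)} "
                        f"!= annotated {annotated}"
                    )
        except (LocusKitError, CnvParseError) as exc:
            report.issues.append(str(exc))
    return report
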