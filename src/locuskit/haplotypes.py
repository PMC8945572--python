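"""Per-haplotype gene content and diffs against the reference haplotype A.

A haplotype is one observed gene-content configuration of a CNV region (or of
a whole locus).  The main line of a locus representation is conventionally
haplotype A; other haplotypes are described relative to it as insertions and
deletions.  Presence takes three regular values — ``present`` (carried, also
in A), ``absent`` (deleted relative to A), ``inserted`` (carried although
absent in A) — plus ``exchanged`` for a gene carried in replaced form, which
has no observed instance in the human tables but is representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable

from .cnv import CnvDefinition, CnvStatus
from .errors import MissingGeneError, MissingHaplotypeError, ValidationError
from .genes import GeneOrderTable, GeneRecord, RawTable, _record_from_row, read_table


class Presence(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    INSERTED = "inserted"
    EXCHANGED = "exchanged"

    @property
    def carried(self) -> bool:
        """Whether the gene is physically present in the haplotype."""
        return self is not Presence.ABSENT


REFERENCE = "A"


@dataclass(frozen=True)
class HaplotypeRow:
    gene: GeneRecord
    presence: dict[str, Presence]

    def __getitem__(self, label: str) -> Presence:
        try:
            return self.presence[label]
        except KeyError as exc:
            raise MissingHaplotypeError(f"unknown haplotype {label!r}") from exc


@dataclass
class HaplotypeTable:
    """Presence/absence/insertion status of genes across named haplotypes."""

    haplotype_ids: list[str]
    rows: list[HaplotypeRow] = field(default_factory=list)
    cnv: CnvDefinition | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if REFERENCE not in self.haplotype_ids:
            raise ValidationError("haplotype table needs the reference haplotype A")
        for row in self.rows:
            missing = [h for h in self.haplotype_ids if h not in row.presence]
            if missing:
                raise ValidationError(
                    f"{row.gene.name}: missing haplotype columns {missing}"
                )
            ref = row.presence[REFERENCE]
            for label, value in row.presence.items():
                if value is Presence.INSERTED and ref is not Presence.ABSENT:
                    raise ValidationError(
                        f"{row.gene.name}: inserted in {label} but not absent in A"
                    )
            if ref is Presence.INSERTED:
                raise ValidationError(
                    f"{row.gene.name}: reference haplotype A cannot be 'inserted'"
                )

    def check_label(self, label: str) -> None:
        if label not in self.haplotype_ids:
            raise MissingHaplotypeError(f"unknown haplotype {label!r}")

    def validate_against(self, table: GeneOrderTable) -> None:
        """Every gene of the haplotype table must exist in the gene-order table."""
        for row in self.rows:
            if row.gene.name.raw_symbol not in table:
                raise MissingGeneError(
                    f"{row.gene.name} not in the {table.locus} gene-order table"
                )


@dataclass(frozen=True)
class HaplotypeDiff:
    """Genes whose status differs between two haplotypes."""

    versus: tuple[str, str]
    changes: tuple[tuple[GeneRecord, CnvStatus], ...]

    def genes(self, letter: str) -> list[str]:
        return [g.name.raw_symbol for g, s in self.changes if s.letter == letter]

    def __len__(self) -> int:
        return len(self.changes)


def diff_haplotypes(t: HaplotypeTable, a: str, b: str) -> HaplotypeDiff:
    """Diff haplotype ``b`` against ``a``.

    A gene carried in ``a`` but not in ``b`` is a deletion (d); carried in
    ``b`` but not in ``a`` an insertion (i); carried in both but exchanged on
    exactly one side an exchange (e).  Genes with identical status never
    appear.
    """
    t.check_label(a)
    t.check_label(b)
    changes: list[tuple[GeneRecord, CnvStatus]] = []
    for row in t.rows:
        pa, pb = row[a], row[b]
        if pa.carried and not pb.carried:
            changes.append((row.gene, CnvStatus("d")))
        elif pb.carried and not pa.carried:
            changes.append((row.gene, CnvStatus("i")))
        elif pa.carried and pb.carried and (pa is Presence.EXCHANGED) != (
            pb is Presence.EXCHANGED
        ):
            changes.append((row.gene, CnvStatus("e")))
    return HaplotypeDiff(versus=(a, b), changes=tuple(changes))


def haplotype_gene_count(
    t: HaplotypeTable,
    label: str,
    predicate: Callable[[GeneRecord], bool] | None = None,
) -> int:
    """Number of genes carried by a haplotype, optionally filtered."""
    t.check_label(label)
    return sum(
        1
        for row in t.rows
        if row[label].carried and (predicate is None or predicate(row.gene))
    )


def haplotype_range_summary(
    t: HaplotypeTable,
    predicate: Callable[[GeneRecord], bool] | None = None,
) -> tuple[int, int]:
    """(min, max) of the per-haplotype gene count over all haplotypes."""
    counts = [haplotype_gene_count(t, h, predicate) for h in t.haplotype_ids]
    return min(counts), max(counts)


# ---------------------------------------------------------------------------
# TSV I/O


def _table_from_raw(raw: RawTable, path: str | Path, cnv: CnvDefinition | None) -> HaplotypeTable:
    labels = raw.haplotype_columns
    if not labels:
        raise ValidationError(f"{path}: no haplotype columns")
    rows = []
    for row in raw.rows:
        gene = _record_from_row(row, path)
        presence = {}
        for label in labels:
            value = row.get(label, "").strip().lower()
            if not value:
                raise ValidationError(
                    f"{path}: {row['gene_name']}: empty presence for haplotype {label}"
                )
            try:
                presence[label] = Presence(value)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: {row['gene_name']}: bad presence value {value!r}"
                ) from exc
        rows.append(HaplotypeRow(gene=gene, presence=presence))
    return HaplotypeTable(haplotype_ids=labels, rows=rows, cnv=cnv)


def load_haplotype_table(path: str | Path, cnv: CnvDefinition | None = None) -> HaplotypeTable:
    """Load a haplotype TSV: gene columns plus one presence column per haplotype."""
    return _table_from_raw(read_table(path), path, cnv)


def save_haplotype_table(t: HaplotypeTable, path: str | Path, *, species: str = "",
                         locus: str = "") -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        if species:
            fh.write(f"# species: {species}\n")
        if locus:
            fh.write(f"# locus: {locus}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene_name", "functionality", "order", "orientation", "cnv_role"]
            + list(t.haplotype_ids)
        )
        for row in t.rows:
            g = row.gene
            writer.writerow(
                [
                    g.name.raw_symbol,
                    str(g.functionality),
                    str(g.order),
                    g.orientation.value,
                    g.cnv_role or "",
                ]
                + [row.presence[h].value for h in t.haplotype_ids]
            )
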