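"""Chromosome <-> locus coordinate mapping for forward and reverse loci.

A locus reference sequence is presented in its own 5'->3' orientation: for a
forward (FWD) locus this matches the chromosome, for a reverse (REV) locus it
is the reverse complement.  All coordinates are 1-based inclusive; only
positions are mapped — no nucleotide complementation is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CoordinateError, ValidationError

FWD = "FWD"
REV = "REV"


@dataclass(frozen=True)
class LocusFrame:
    """Extent and orientation of a locus on its chromosome."""

    chrom_start: int
    chrom_end: int
    orientation: str

    def __post_init__(self) -> None:
        if self.chrom_start < 1 or self.chrom_end < self.chrom_start:
            raise ValidationError("frame must satisfy 1 <= chrom_start <= chrom_end")
        if self.orientation not in (FWD, REV):
            raise ValidationError(f"orientation must be FWD or REV, got {self.orientation!r}")


def locus_length(f: LocusFrame) -> int:
    return f.chrom_end - f.chrom_start + 1


def chrom_to_locus(f: LocusFrame, pos: int) -> int:
    """Map a chromosome position into the locus's own coordinates.

    A REV locus counts from its 3' chromosome end: the highest chromosome
    position is locus position 1.
    """
    if not f.chrom_start <= pos <= f.chrom_end:
        raise CoordinateError(
            f"position {pos} outside frame {f.chrom_start}..{f.chrom_end}"
        )
    if f.orientation == FWD:
        return pos - f.chrom_start + 1
    return f.chrom_end - pos + 1


def locus_to_chrom(f: LocusFrame, pos: int) -> int:
    """Exact inverse of :func:`chrom_to_locus`."""
    n = locus_length(f)
    if not 1 <= pos <= n:
        raise CoordinateError(f"locus position {pos} outside 1..{n}")
    if f.orientation == FWD:
        return f.chrom_start + pos - 1
    return f.chrom_end - pos + 1
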