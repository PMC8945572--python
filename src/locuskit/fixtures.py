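"""Access to the packaged human locus fixtures and worked reference records.

The shipped TSVs transcribe the published gene-order tables of the seven
human IG/TR loci (the nested TRA/TRD pair shares one table), the locus-borne
table, and the two heavy-chain CNV haplotype panels.  The rhesus macaque IGL
locus-unit record used in the worked flat-file example is built here too.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .genes import BorneEntry, GeneOrderTable, load_bornes, load_gene_order
from .haplotypes import HaplotypeTable, load_haplotype_table
from .locus_unit import AccessionId, AssemblyRef, LocusOrientation, LocusUnit, Positions

#: loci with a shipped gene-order fixture (TRA covers the nested TRD locus)
HUMAN_LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRG")

_FILES = {
    "IGH": "human_IGH.tsv",
    "IGK": "human_IGK.tsv",
    "IGL": "human_IGL.tsv",
    "TRA": "human_TRA_TRD.tsv",
    "TRD": "human_TRA_TRD.tsv",
    "TRB": "human_TRB.tsv",
    "TRG": "human_TRG.tsv",
}

_HAPLOTYPE_FILES = {
    "IGK": "human_IGK.tsv",
    "IGL": "human_IGL.tsv",
    "TRB": "human_TRB.tsv",
    "TRG": "human_TRG.tsv",
    "IGH_CNV3": "human_IGH_CNV3_haplotypes_synthetic.tsv",
    "IGH_CNV7": "human_IGH_CNV7_haplotypes.tsv",
}


def fixture_path(filename: str) -> Path:
    return Path(resources.files("locuskit.data") / filename)


def fixture_paths() -> list[Path]:
    """Paths of all shipped fixture TSVs."""
    names = sorted(set(_FILES.values()) | set(_HAPLOTYPE_FILES.values()) | {"bornes.tsv"})
    return [fixture_path(n) for n in names]


def load_human(locus: str) -> GeneOrderTable:
    """Load the human gene-order table for a locus code (TRD maps to TRA/TRD)."""
    if locus not in _FILES:
        raise KeyError(f"no fixture for locus {locus!r}; choose from {HUMAN_LOCI}")
    return load_gene_order(fixture_path(_FILES[locus]))


def load_human_haplotypes(key: str) -> HaplotypeTable:
    """Load a haplotype panel: a locus code or "IGH_CNV3"/"IGH_CNV7"."""
    if key not in _HAPLOTYPE_FILES:
        raise KeyError(
            f"no haplotype fixture {key!r}; choose from {sorted(_HAPLOTYPE_FILES)}"
        )
    return load_haplotype_table(fixture_path(_HAPLOTYPE_FILES[key]))


def load_human_bornes() -> list[BorneEntry]:
    return load_bornes(fixture_path("bornes.tsv"))


def macmul_igl_locus_unit() -> tuple[AssemblyRef, LocusUnit, AccessionId]:
    """The rhesus macaque IGL locus reference record (worked example)."""
    unit = LocusUnit(
        locus_name="Macaca mulatta IGL",
        locus_id="Macmul_IGL_2",
        chromosome="10",
        length_bp=1300711,
        orientation=LocusOrientation.REV,
        positions=Positions(
            accession="CM014345.1", start=29621424, end=30922134, complement=True
        ),
        five_prime_gene="IGLV(IV)-127",
        three_prime_gene="IGLC7",
        five_prime_borne="TOP3B",
        three_prime_borne="RSPH14",
    )
    assembly = AssemblyRef(
        organism="Macaca mulatta",
        common_name="Rhesus monkey",
        taxon_id=9544,
        isolate="AG07107 single Indian origin rhesus female",
        assembly_name="Mmul_10",
        assembly_uid="2345051",
        genbank_assembly_id="GCA_003339765.3",
        refseq_assembly_id="GCF_003339765.1",
    )
    return assembly, unit, AccessionId("IMGT000062")
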