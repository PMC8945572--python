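"""Locus-unit records: IDs, flat-file rendering/parsing, definition lines."""

import pytest
from hypothesis import given, strategies as st

from locuskit import (
    AccessionId,
    AssemblyRef,
    FlatFileParseError,
    InputError,
    LocusOrientation,
    LocusUnit,
    Positions,
    ValidationError,
    fixtures,
    make_locus_id,
    parse_definition_line,
    parse_locus_unit,
    render_definition_line,
    render_locus_unit,
)


class TestLocusId:
    @pytest.mark.parametrize(
        "args,expected",
        [
            (("Macaca", "mulatta", "IGL", 2), "Macmul_IGL_2"),
            (("Homo", "sapiens", "IGH", 1), "Homsap_IGH_1"),
            (("Canis", "lupus", "TRB", 1, "familiaris"), "Canlupfam_TRB_1"),
        ],
    )
    def test_taxon_abbreviation_rule(self, args, expected):
        assert make_locus_id(*args) == expected

    def test_short_names_rejected(self):
        with pytest.raises(InputError):
            make_locus_id("Ab", "cdefg", "IGH", 1)


class TestAccession:
    def test_shape_enforced(self):
        AccessionId("IMGT000062")
        for bad in ("IMGT62", "IMGT0000620", "LIGM000062"):
            with pytest.raises(ValidationError):
                AccessionId(bad)


@pytest.fixture(scope="module")
def macmul():
    return fixtures.macmul_igl_locus_unit()


class TestFlatFile:
    def test_worked_example_qualifier_values(self, macmul):
        _, unit, _ = macmul
        text = "\n".join(render_locus_unit(unit))
        for fragment in (
            "FT   IMGT-LOCUS-UNIT 1..1300711",
            '/IMGT_locus_3prime_borne="RSPH14"',
            '/IMGT_locus_3prime_gene="IGLC7"',
            '/IMGT_locus_5prime_borne="TOP3B"',
            '/IMGT_locus_5prime_gene="IGLV(IV)-127"',
            '/IMGT_locus_ID="Macmul_IGL_2"',
            '/IMGT_locus_chromosome="10"',
            '/IMGT_locus_length="1300711 bp"',
            '/IMGT_locus_name="Macaca mulatta IGL"',
            '/IMGT_locus_orientation="reverse (REV)"',
            '/IMGT_locus_positions="CM014345.1',
        ):
            assert fragment in text

    def test_qualifiers_sorted_bytewise(self, macmul):
        _, unit, _ = macmul
        names = [
            line.split("/")[1].split("=")[0]
            for line in render_locus_unit(unit)
            if "=" in line and "/" in line
        ]
        assert names == sorted(names)
        assert names[0] == "IMGT_locus_3prime_borne"
        assert names[-1] == "IMGT_locus_positions"

    def test_rendering_is_deterministic(self, macmul):
        _, unit, _ = macmul
        assert render_locus_unit(unit) == render_locus_unit(unit)

    def test_parse_render_identity(self, macmul):
        _, unit, _ = macmul
        assert parse_locus_unit(render_locus_unit(unit)) == unit

    def test_parse_accepts_typographic_quotes(self):
        block = [
            "FT   IMGT-LOCUS-UNIT 1..10",
            "FT                   /IMGT_locus_3prime_borne=“B3”",
            "FT                   /IMGT_locus_3prime_gene=“IGLC1”",
            "FT                   /IMGT_locus_5prime_borne=“B5”",
            "FT                   /IMGT_locus_5prime_gene=“IGLV1-2”",
            "FT                   /IMGT_locus_ID=“Homsap_IGL_9”",
            "FT                   /IMGT_locus_chromosome=“22”",
            "FT                   /IMGT_locus_length=“10 bp”",
            "FT                   /IMGT_locus_name=“Homo sapiens IGL”",
            "FT                   /IMGT_locus_orientation=“forward (FWD)”",
            "FT                   /IMGT_locus_positions=“X (1-10)”",
        ]
        unit = parse_locus_unit(block)
        assert unit.span == (1, 10)
        assert unit.positions == Positions("X", 1, 10, False)

    def test_length_positions_mismatch_rejected(self, macmul):
        _, unit, _ = macmul
        lines = [
            line.replace("1300711 bp", "100 bp").replace("1..1300711", "1..100")
            for line in render_locus_unit(unit)
        ]
        with pytest.raises((FlatFileParseError, ValidationError)):
            parse_locus_unit(lines)

    def test_missing_mandatory_qualifier_named(self, macmul):
        _, unit, _ = macmul
        lines = [l for l in render_locus_unit(unit) if "chromosome" not in l]
        with pytest.raises(FlatFileParseError, match="IMGT_locus_chromosome"):
            parse_locus_unit(lines)

    def test_construction_enforces_length_invariant(self):
        with pytest.raises(ValidationError):
            LocusUnit(
                locus_name="Homo sapiens IGL",
                locus_id="Homsap_IGL_1",
                chromosome="22",
                length_bp=99,
                orientation=LocusOrientation.FWD,
                positions=Positions("X", 1, 10, False),
                five_prime_gene="IGLV1-2",
                three_prime_gene="IGLC1",
                five_prime_borne="TOP3B",
                three_prime_borne="RSPH14",
            )

    @given(start=st.integers(1, 10**8), length=st.integers(1, 10**7),
           rev=st.booleans())
    def test_randomized_round_trip(self, start, length, rev):
        unit = LocusUnit(
            locus_name="Homo sapiens TRB",
            locus_id="Homsap_TRB_1",
            chromosome="7",
            length_bp=length,
            orientation=LocusOrientation.REV if rev else LocusOrientation.FWD,
            positions=Positions("AC245166.2", start, start + length - 1, rev),
            five_prime_gene="TRBV1",
            three_prime_gene="TRBC2",
            five_prime_borne="MOXD2",
            three_prime_borne="EPHB6",
        )
        assert parse_locus_unit(render_locus_unit(unit)) == unit

    def test_borne_check_against_reference_table(self, macmul, bornes):
        _, unit, _ = macmul
        assert unit.check_bornes(bornes) == []
        odd = LocusUnit(
            locus_name="Homo sapiens TRB",
            locus_id="Homsap_TRB_1",
            chromosome="7",
            length_bp=10,
            orientation=LocusOrientation.FWD,
            positions=Positions("X", 1, 10, False),
            five_prime_gene="TRBV1",
            three_prime_gene="TRBC2",
            five_prime_borne="NOTAGENE",
            three_prime_borne="EPHB6",
        )
        warnings = odd.check_bornes(bornes)
        assert len(warnings) == 1 and "NOTAGENE" in warnings[0]


class TestDefinitionLine:
    def test_worked_example_fields(self, macmul):
        assembly, unit, acc = macmul
        line = render_definition_line(assembly, unit, acc)
        assert "IMGT locus ID: Macmul_IGL_2" in line
        assert "chromosome 10: CM014345.1 (29621424-30922134, complement)" in line
        assert "taxon:9544" in line
        assert "assembly Mmul_10" in line

    def test_round_trip_through_parser(self, macmul):
        assembly, unit, acc = macmul
        fields = parse_definition_line(render_definition_line(assembly, unit, acc))
        assert fields["locus_id"] == unit.locus_id
        assert fields["organism"] == assembly.organism
        assert fields["genbank_assembly_id"] == assembly.genbank_assembly_id
        assert int(fields["start"]) == unit.positions.start
        assert fields["complement"] == "yes"

    def test_synthetic_record_round_trips(self):
        unit = LocusUnit(
            locus_name="Homo sapiens TRG",
            locus_id="Homsap_TRG_1",
            chromosome="7",
            length_bp=160000,
            orientation=LocusOrientation.REV,
            positions=Positions("NC_000007.14", 38240024, 38400023, True),
            five_prime_gene="TRGV1",
            three_prime_gene="TRGC2",
            five_prime_borne="AMPH",
            three_prime_borne="STARD3NL",
        )
        assembly = AssemblyRef(
            organism="Homo sapiens",
            common_name="human",
            taxon_id=9606,
            isolate="reference",
            assembly_name="GRCh38",
            genbank_assembly_id="GCA_000001405.15",
            refseq_assembly_id="GCF_000001405.26",
        )
        acc = AccessionId("IMGT000999")
        fields = parse_definition_line(render_definition_line(assembly, unit, acc))
        assert fields["accession"] == "IMGT000999"
        assert fields["assembly_name"] == "GRCh38"
        assert fields["assembly_uid"] == ""
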