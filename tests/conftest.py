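import pytest
from hypothesis import settings

from locuskit import fixtures

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRG")


@pytest.fixture(scope="session")
def tables():
    """Human gene-order tables, keyed by locus code."""
    return {locus: fixtures.load_human(locus) for locus in LOCI}


@pytest.fixture(scope="session")
def igh(tables):
    return tables["IGH"]


@pytest.fixture(scope="session")
def haplotype_tables():
    return {key: fixtures.load_human_haplotypes(key)
            for key in ("IGK", "IGL", "TRB", "TRG", "IGH_CNV3", "IGH_CNV7")}


@pytest.fixture(scope="session")
def bornes():
    return fixtures.load_human_bornes()
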