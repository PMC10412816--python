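import pytest

from cyp2d6es.alleles import load_allele_table
from cyp2d6es.population import PopulationModel
from cyp2d6es.types import CnvCall, SnpPanelGenotype


@pytest.fixture(scope="session")
def table():
    return load_allele_table()


@pytest.fixture(scope="session")
def pop():
    return PopulationModel.from_cohort_table("combined")


@pytest.fixture(scope="session")
def make_genotype(table):
    """Build an unphased panel genotype from per-rsID overrides.

    Overrides are (a, b) allele pairs; everything else is homozygous
    reference.
    """

    def _make(sample_id="S", **overrides):
        calls = {r: (a, a) for r, a in table.reference_calls().items()}
        calls.update(overrides)
        return SnpPanelGenotype(sample_id, calls)

    return _make


@pytest.fixture
def cnv2():
    return CnvCall(2, 2)
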