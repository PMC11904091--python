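import pytest
from hypothesis import settings

from trioscope import (
    Pedigree,
    PipelineConfig,
    Sex,
    SimConfig,
    simulate_cohort,
)
from trioscope.constraint import annotate_genes
from trioscope.splice import annotate_gene_context

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def male_trio():
    return Pedigree("FAM1", "P1", "M1", "F1", Sex.MALE)


@pytest.fixture
def female_trio():
    return Pedigree("FAM2", "P2", "M2", "F2", Sex.FEMALE)


def prepare_cohort(config: SimConfig):
    """Simulate a cohort and attach gene-context and constraint annotations."""
    cohort = simulate_cohort(config)
    for trio in cohort.trios:
        annotate_gene_context(trio.variants, cohort.gene_models)
        annotate_genes(trio.variants, cohort.constraint_table)
    return cohort


@pytest.fixture(scope="session")
def cohort30():
    return prepare_cohort(SimConfig(seed=1, n_trios=30))


@pytest.fixture(scope="session")
def cohort30_config(cohort30):
    return PipelineConfig(panels=cohort30.panels)
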