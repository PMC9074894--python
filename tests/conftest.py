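import numpy as np
import pytest

import epimitm as em

#: default planted triangle: log-PAH -> CpG -> CBCL-social (count outcome);
#: closed-form mediated proportion 0.42 / (0.42 + 0.48) = 0.4667
PLANTED_COUNT = em.PlantedPathConfig(
    exposure="pah_log", outcome="cbcl_social_age7", a=0.6, b=0.7, c_direct=0.48
)
#: a continuous (IQ-like) triangle on a different exposure and outcome
PLANTED_CONTINUOUS = em.PlantedPathConfig(
    exposure="bpa_log", outcome="iq_age7", a=0.5, b=6.0, c_direct=4.0
)


def cell_frame(cohort):
    cells = cohort[[c for c in cohort.columns if c.startswith("cell_")]]
    return cells.rename(columns=lambda c: c.removeprefix("cell_"))


def preprocess_to_residuals(cohort, meth):
    """beta -> M -> cell-residual, the pipeline's methylation path."""
    return em.residualize_cells(em.beta_to_m(meth), cell_frame(cohort))


@pytest.fixture(scope="session")
def planted_config():
    return em.SimConfig(n_samples=300, seed=11, planted=(PLANTED_COUNT,))


@pytest.fixture(scope="session")
def planted_cohort(planted_config):
    return em.generate_cohort(planted_config)


@pytest.fixture(scope="session")
def planted_residuals(planted_cohort):
    cohort, meth, _ = planted_cohort
    return preprocess_to_residuals(cohort, meth)


@pytest.fixture(scope="session")
def planted_fixture(planted_config):
    return em.generate_pathway_fixture(planted_config)


@pytest.fixture(scope="session")
def null_config():
    return em.SimConfig(n_samples=200, n_cpgs=60, seed=5)


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return em.generate_cohort(null_config)
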