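import warnings

import pytest

from mrith.config import SimulationConfig
from mrith.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient cohort reused by read-only tests."""
    cfg = SimulationConfig(n_patients=4, regions_per_patient=(3, 4),
                           n_cpg_bins=60, n_genes=60, n_epiallele_loci=8,
                           seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 2-patient cohort for fast structural tests."""
    cfg = SimulationConfig(n_patients=2, regions_per_patient=(2, 3),
                           n_clones=(2, 3), n_mutations=8, n_cpg_bins=20,
                           n_genes=25, n_epiallele_loci=4, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(cfg)
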