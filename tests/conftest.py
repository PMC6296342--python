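import numpy as np
import pytest

from methmod import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort exercising all probe kinds: 25 loci, 120 samples."""
    cfg = GeneratorConfig(n_samples=120, n_hyper=8, n_hypo=12, n_null=5, seed=11)
    matrix, pheno, reference, truth = simulate_cohort(cfg)
    return cfg, matrix, pheno, reference, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The study-conditions cohort: 180 samples, 300 loci (66/205/29)."""
    cfg = GeneratorConfig(seed=2024)
    matrix, pheno, reference, truth = simulate_cohort(cfg)
    return cfg, matrix, pheno, reference, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
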