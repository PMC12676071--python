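import dataclasses

import numpy as np
import pytest

from gametecross import SimConfig, SinglePollenStudy, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Noisy 20-individual cohort at reduced marker density, fixed seed."""
    cfg = dataclasses.replace(
        SimConfig(), n_individuals=20, n_markers_per_chrom=200, seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    return SinglePollenStudy.from_cohort(small_cohort).fit()


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero-noise 30-individual cohort (no error, no missingness, no failures)."""
    cfg = dataclasses.replace(
        SimConfig(),
        n_individuals=30,
        n_markers_per_chrom=300,
        error_rate=0.0,
        missing_rate=0.0,
        nucleus_failure_rate=0.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_results(clean_cohort):
    return SinglePollenStudy.from_cohort(clean_cohort).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
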