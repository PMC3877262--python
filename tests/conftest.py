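import numpy as np
import pytest

import mirentropy as me


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with one planted module (fast enough for unit tests)."""
    config = me.SimulationConfig(
        n_genes=150, n_mirnas=60, n_samples_per_condition=40, n_modules=6,
        module_size_range=(4, 6), n_planted=1, background_edge_rate=0.02,
        seed=42,
    )
    return me.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_screen(small_cohort):
    cohort = small_cohort
    modules, _ = me.build_modules(cohort.gene_sets, cohort.interactions,
                                  cohort.mrna, cohort.mirna)
    data = me.prepare_screen(cohort.mrna, cohort.mirna, cohort.groups,
                             cohort.interactions,
                             cohort.config.condition_a, cohort.config.condition_b)
    return cohort, modules, data


def gaussian_pair(rng, r, n):
    """Bivariate standard normal sample with correlation r."""
    cov = np.array([[1.0, r], [r, 1.0]])
    return rng.multivariate_normal([0.0, 0.0], cov, size=n).T
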