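import math

import numpy as np
import pytest
from scipy import stats

import mirentropy as me
from mirentropy.downstream import (
    DownstreamConfig,
    dependency_network,
    fisher_combine,
    interaction_dependency,
    screen_downstream,
)
from mirentropy.synthetic_data import simulate_modulator_triplet

from conftest import gaussian_pair


# --- Fisher combination -----------------------------------------------------

def test_fisher_two_pvalues_closed_form():
    statistic, combined = fisher_combine([0.05, 0.05])
    assert statistic == pytest.approx(-4.0 * math.log(0.05), abs=1e-10)
    assert statistic == pytest.approx(11.983, abs=1e-3)
    # chi-square upper tail with 4 df: exp(-x/2) * (1 + x/2)
    expected = math.exp(-statistic / 2) * (1 + statistic / 2)
    assert combined == pytest.approx(expected, abs=1e-10)
    assert combined == pytest.approx(0.0175, abs=1e-4)


def test_fisher_single_trivial_pvalue():
    statistic, combined = fisher_combine([1.0])
    assert statistic == 0.0
    assert combined == 1.0


def test_fisher_rejects_invalid():
    with pytest.raises(ValueError):
        fisher_combine([])
    with pytest.raises(ValueError, match="lie in"):
        fisher_combine([0.0, 0.5])


def test_fisher_matches_independent_oracle(rng):
    """−2Σln p with the closed-form chi-square tail for even df."""
    for _ in range(1000):
        k = int(rng.integers(1, 7))
        p = rng.random(k) * 0.999 + 0.001
        statistic, combined = fisher_combine(p)
        stat_oracle = -2.0 * math.fsum(math.log(v) for v in p)
        half = stat_oracle / 2.0
        tail = math.exp(-half) * math.fsum(half**i / math.factorial(i)
                                           for i in range(k))
        assert statistic == pytest.approx(stat_oracle, abs=1e-10)
        assert combined == pytest.approx(tail, abs=1e-10)


def test_fisher_uniform_inputs_give_uniform_output(rng):
    combined = [fisher_combine(rng.random(5))[1] for _ in range(1000)]
    assert stats.kstest(combined, "uniform").pvalue > 0.01


# --- per-triplet permutation test -------------------------------------------

def test_interaction_dependency_deterministic(rng):
    x, y, z = simulate_modulator_triplet(80, rng)
    a = interaction_dependency(x, y, z, n_permutations=100, seed=3)
    b = interaction_dependency(x, y, z, n_permutations=100, seed=3)
    assert (a.cmi, a.delta_stat, a.p_value) == (b.cmi, b.delta_stat, b.p_value)
    assert a.testable and 0 < a.p_value <= 1


def test_interaction_dependency_constant_profile_untestable(rng):
    x = rng.standard_normal(50)
    res = interaction_dependency(x, np.full(50, 3.3), x + 1,
                                 n_permutations=100, seed=0)
    assert not res.testable
    assert math.isnan(res.p_value)


def test_interaction_dependency_validation(rng):
    x, y, z = rng.standard_normal((3, 50))
    with pytest.raises(ValueError, match="statistic"):
        interaction_dependency(x, y, z, n_permutations=100, statistic="ratio")
    with pytest.raises(ValueError, match="n_permutations"):
        interaction_dependency(x, y, z, n_permutations=10)
    with pytest.raises(ValueError, match="lengths"):
        interaction_dependency(x, y, z[:-1], n_permutations=100)


def test_modulated_triplet_detected(rng):
    """A protein-gated miRNA–target link yields a small permutation p."""
    hits = 0
    for _ in range(10):
        x, y, z = simulate_modulator_triplet(200, rng)
        res = interaction_dependency(x, y, z, n_permutations=100, seed=rng)
        hits += res.p_value <= 0.05
    assert hits >= 8


def test_independent_protein_not_flagged(rng):
    """With z independent of the (x, y) link, p-values stay moderate."""
    ps = []
    for _ in range(10):
        x, y = gaussian_pair(rng, 0.6, 150)
        z = rng.standard_normal(150)
        ps.append(interaction_dependency(x, y, z, n_permutations=100,
                                         seed=rng).p_value)
    assert np.mean(np.array(ps) <= 0.05) <= 0.3


# --- complex-level screen ---------------------------------------------------

@pytest.fixture(scope="module")
def downstream_cohort():
    config = me.SimulationConfig(
        n_genes=60, n_mirnas=12, n_samples_per_condition=80, n_modules=4,
        module_size_range=(3, 4), n_planted=1, background_edge_rate=0.015,
        n_modulator_triplets=3, coupling=0.0, seed=7,
    )
    cohort = me.simulate_cohort(config)
    modules, _ = me.build_modules(cohort.gene_sets, cohort.interactions,
                                  cohort.mrna, cohort.mirna)
    cond_a, cond_b = me.align_conditions(
        cohort.mrna, cohort.mirna, cohort.groups,
        config.condition_a, config.condition_b,
    )
    return cohort, modules, cond_b


def test_screen_bookkeeping_and_determinism(downstream_cohort):
    cohort, modules, cond = downstream_cohort
    config = DownstreamConfig(n_permutations=100, seed=9)
    deps, summaries = screen_downstream(modules[:2], cohort.interactions,
                                        cond, config)
    deps2, summaries2 = screen_downstream(modules[:2][::-1], cohort.interactions,
                                          cond, config)
    assert deps == deps2                      # order invariant
    assert sorted(s.set_id for s in summaries) == sorted(s.set_id for s in summaries2)
    for s in summaries:
        claimed = [d for d in deps if s.set_id in d.complex_ids and d.testable]
        assert s.k == len(claimed)
    module = modules[0]
    for d in deps:
        if module.set_id in d.complex_ids:
            assert d.target_id not in module.proteins  # self-targets excluded


def test_modulated_complex_has_smallest_combined_p(downstream_cohort):
    cohort, modules, cond = downstream_cohort
    config = DownstreamConfig(n_permutations=100, seed=2)
    deps, summaries = screen_downstream(modules, cohort.interactions, cond, config)
    planted_set = cohort.truth.modulator_triplets[0].set_id
    testable = [s for s in summaries if s.testable]
    best = min(testable, key=lambda s: s.combined_p)
    assert best.set_id == planted_set


def test_screen_validation(downstream_cohort):
    cohort, modules, cond = downstream_cohort
    with pytest.raises(ValueError, match="no complexes"):
        screen_downstream([], cohort.interactions, cond)


# --- network export ---------------------------------------------------------

def test_dependency_network(downstream_cohort):
    cohort, modules, cond = downstream_cohort
    config = DownstreamConfig(n_permutations=100, seed=9)
    deps, _ = screen_downstream(modules[:1], cohort.interactions, cond, config)
    empty = dependency_network(deps, alpha=1e-9)
    assert list(empty.columns) == ["protein_id", "target_id", "mirna_id", "p_value"]
    assert empty.empty
    full = dependency_network(deps, alpha=1.0)
    assert len(full) == sum(d.testable for d in deps)
    again = dependency_network(deps, alpha=1.0)
    assert full.equals(again)
    with pytest.raises(ValueError, match="alpha"):
        dependency_network(deps, alpha=0.0)
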