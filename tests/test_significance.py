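import numpy as np
import pytest

import mirentropy as me
from mirentropy.significance import (
    PermutationConfig,
    adjust_pvalues,
    empirical_pvalue,
    null_delta_distribution,
    results_table,
    run_screen,
)


# --- empirical p-values ----------------------------------------------------

def test_pvalue_add_one_extremes(rng):
    null = rng.random(999)
    assert empirical_pvalue(null.max() + 1.0, null) == pytest.approx(1 / 1000)
    assert empirical_pvalue(null.min(), null) == 1.0


def test_pvalue_at_median(rng):
    null = rng.random(999)
    p = empirical_pvalue(np.median(null), null)
    assert p == pytest.approx(0.5, abs=1.5e-3)


def test_pvalue_empty_null():
    with pytest.raises(ValueError, match="empty"):
        empirical_pvalue(0.5, np.array([]))


# --- multiple testing ------------------------------------------------------

def test_bonferroni_examples():
    np.testing.assert_allclose(adjust_pvalues([0.001, 0.5], "bonferroni"),
                               [0.002, 1.0])
    np.testing.assert_allclose(adjust_pvalues([0.3], "bonferroni"), [0.3])


def test_benjamini_hochberg_step_up():
    # hand computation: sorted p * k / rank, cumulative minimum from the top
    np.testing.assert_allclose(
        adjust_pvalues([0.01, 0.02, 0.9], "benjamini-hochberg"),
        [0.03, 0.03, 0.9],
    )


def test_adjust_pvalues_matches_hand_oracle(rng):
    p = rng.random(25)

    def bh_oracle(p):
        k = len(p)
        order = np.argsort(p)
        adj = np.empty(k)
        running = 1.0
        for rank in range(k, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * k / rank)
            adj[i] = running
        return adj

    np.testing.assert_allclose(adjust_pvalues(p, "benjamini-hochberg"),
                               bh_oracle(p), atol=1e-12)
    np.testing.assert_allclose(adjust_pvalues(p, "bonferroni"),
                               np.minimum(p * 25, 1.0), atol=1e-12)


def test_adjust_pvalues_validation():
    with pytest.raises(ValueError, match="correction"):
        adjust_pvalues([0.5], "holm")
    with pytest.raises(ValueError, match="lie in"):
        adjust_pvalues([0.0, 0.5], "bonferroni")


def test_permutation_config_validation():
    with pytest.raises(ValueError, match="n_permutations"):
        PermutationConfig(n_permutations=50)
    with pytest.raises(ValueError, match="background"):
        PermutationConfig(background="degree-matched")
    with pytest.raises(ValueError, match="correction"):
        PermutationConfig(correction="sidak")


# --- the permutation null --------------------------------------------------

def test_null_distribution_deterministic(small_screen):
    _, _, data = small_screen
    config = PermutationConfig(n_permutations=100, seed=5)
    a = null_delta_distribution(4, data, config)
    b = null_delta_distribution(4, data, config)
    np.testing.assert_array_equal(a, b)
    assert a.size == 100
    assert np.all(a >= 0)


def test_null_requires_large_pool(small_screen):
    _, _, data = small_screen
    config = PermutationConfig(n_permutations=100, seed=5)
    with pytest.raises(ValueError, match="pool"):
        null_delta_distribution(len(data.background_genes), data, config)


# --- the screen ------------------------------------------------------------

def test_run_screen_deterministic_and_order_invariant(small_screen):
    _, modules, data = small_screen
    config = PermutationConfig(n_permutations=100, seed=11)
    table1 = results_table(run_screen(modules, data, config)).to_csv(index=False)
    table2 = results_table(run_screen(modules[::-1], data, config)).to_csv(index=False)
    assert table1 == table2  # byte-identical, independent of input order


def test_run_screen_output_contract(small_screen):
    cohort, modules, data = small_screen
    config = PermutationConfig(n_permutations=100, seed=11)
    results = run_screen(modules, data, config)
    assert len(results) == len(modules)
    for r in results:
        assert 1 / 101 <= r.p_value <= 1.0
        assert r.p_adjusted >= r.p_value
        assert r.p_adjusted <= 1.0
        assert r.n_null_used == 100
    keys = [(r.p_value, -abs(r.delta), r.set_id) for r in results]
    assert keys == sorted(keys)
    with pytest.raises(ValueError, match="at least one module"):
        run_screen([], data, config)


def test_planted_module_ranks_first(small_screen):
    cohort, modules, data = small_screen
    config = PermutationConfig(n_permutations=199, seed=1)
    results = run_screen(modules, data, config)
    assert results[0].set_id == cohort.truth.planted_modules[0]
    assert results[0].z_score > 2.0
    assert results[0].p_gaussian < 0.05
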