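import numpy as np
import pytest

import mirentropy as me
from mirentropy.io_model import ExpressionMatrix, ModuleDefinition
from mirentropy.module_entropy import (
    ConditionMIWorkspace,
    build_module_matrix,
    score_module,
    svd_entropy,
)


# --- spectral entropy -----------------------------------------------------

def test_rank_one_matrix_zero_entropy():
    E, sigma, rho = svd_entropy(np.array([[1.0, 0.0], [0.0, 0.0]]))
    assert E == 0.0
    np.testing.assert_allclose(sigma, [1.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(rho, [1.0, 0.0], atol=1e-12)


def test_isotropic_matrix_maximal_entropy():
    E, _, rho = svd_entropy(np.eye(2))
    assert E == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(rho, [0.5, 0.5], atol=1e-12)


def test_hand_evaluated_spectrum():
    # singular values 2 and 1: rho = (0.8, 0.2), normalized entropy 0.7219
    E, _, rho = svd_entropy(np.array([[2.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
    np.testing.assert_allclose(rho, [0.8, 0.2], atol=1e-12)
    expected = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2)) / np.log(2)
    assert E == pytest.approx(expected, abs=1e-12)
    assert E == pytest.approx(0.7219, abs=1e-4)


def test_single_singular_value_is_zero_by_definition():
    E, _, _ = svd_entropy(np.array([[1.0, 2.0, 3.0]]))
    assert E == 0.0


def test_zero_matrix_warns():
    with pytest.warns(UserWarning, match="zero"):
        E, _, _ = svd_entropy(np.zeros((2, 3)))
    assert E == 0.0


def test_nonfinite_rejected():
    with pytest.raises(ValueError, match="finite"):
        svd_entropy(np.array([[1.0, np.inf]]))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_entropy_invariances(seed):
    rng = np.random.default_rng(seed)
    X = rng.random((4, 7))
    E, _, rho = svd_entropy(X)
    assert rho.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(rho) <= 1e-12)  # non-increasing
    perm = X[rng.permutation(4)][:, rng.permutation(7)]
    assert svd_entropy(perm)[0] == pytest.approx(E, abs=1e-9)
    assert svd_entropy(X.T)[0] == pytest.approx(E, abs=1e-9)
    assert svd_entropy(7.3 * X)[0] == pytest.approx(E, abs=1e-9)


def test_entropy_matches_eigenvalue_oracle():
    """E from eigenvalues of X^T X equals E from singular values."""
    rng = np.random.default_rng(99)
    for _ in range(100):
        m, n = rng.integers(2, 8, size=2)
        X = rng.standard_normal((m, n))
        E, _, _ = svd_entropy(X)
        eigvals = np.clip(np.linalg.eigvalsh(X.T @ X), 0.0, None)
        rho = eigvals / eigvals.sum()
        rho = rho[rho > 1e-15]
        expected = float(-(rho * np.log(rho)).sum() / np.log(min(m, n)))
        assert E == pytest.approx(expected, abs=1e-9)


# --- module matrices ------------------------------------------------------

@pytest.fixture
def toy_condition(rng):
    samples = [f"s{i}" for i in range(40)]
    mrna = ExpressionMatrix(["g1", "g2", "g3"], samples, rng.standard_normal((3, 40)))
    mirna = ExpressionMatrix(["m1", "m2"], samples, rng.standard_normal((2, 40)))
    return mrna, mirna


def test_module_matrix_matches_pairwise_oracle(toy_condition):
    mrna, mirna = toy_condition
    module = ModuleDefinition("C1", ("g1", "g2"), ("m1", "m2"))
    mm = build_module_matrix(module, mrna, mirna)
    oracle = me.pairwise_mi_matrix(
        [mrna.profile("g1"), mrna.profile("g2")],
        [mirna.profile("m1"), mirna.profile("m2")],
    )
    np.testing.assert_allclose(mm.X, oracle, atol=1e-12)


def test_every_cell_computed_without_edge(toy_condition):
    # the matrix covers non-targeted members too
    mrna, mirna = toy_condition
    module = ModuleDefinition("C1", ("g1", "g2"), ("m1",))
    mm = build_module_matrix(module, mrna, mirna)
    assert mm.X.shape == (2, 1)
    assert np.all(np.isfinite(mm.X))


def test_constant_profile_gives_zero_row(rng, caplog):
    samples = [f"s{i}" for i in range(30)]
    values = rng.standard_normal((2, 30))
    values[1] = 4.2
    mrna = ExpressionMatrix(["g1", "g2"], samples, values)
    mirna = ExpressionMatrix(["m1"], samples, rng.standard_normal((1, 30)))
    module = ModuleDefinition("C1", ("g1", "g2"), ("m1",))
    with caplog.at_level("WARNING"):
        mm = build_module_matrix(module, mrna, mirna)
    assert mm.X[1, 0] == 0.0
    assert any("constant" in r.message for r in caplog.records)


def test_missing_feature_raises(toy_condition):
    mrna, mirna = toy_condition
    module = ModuleDefinition("C1", ("g1", "absent"), ("m1",))
    with pytest.raises(KeyError, match="absent"):
        build_module_matrix(module, mrna, mirna)


def test_workspace_path_equals_direct(small_screen):
    cohort, modules, data = small_screen
    module = modules[0]
    direct = build_module_matrix(module, data.cond_a.mrna, data.cond_a.mirna,
                                 data.mi_config)
    cached = build_module_matrix(module, data.cond_a.mrna, data.cond_a.mirna,
                                 workspace=data.workspace_a)
    np.testing.assert_allclose(cached.X, direct.X, atol=1e-12)


# --- module scoring -------------------------------------------------------

def test_identical_conditions_zero_delta(toy_condition):
    mrna, mirna = toy_condition
    cond = me.ConditionData("same", mrna, mirna)
    module = ModuleDefinition("C1", ("g1", "g2", "g3"), ("m1", "m2"))
    result = score_module(module, cond, cond)
    assert result.delta == 0.0


def test_label_swap_symmetry(small_screen):
    cohort, modules, data = small_screen
    module = modules[0]
    fwd_abs = score_module(module, data.cond_a, data.cond_b)
    rev_abs = score_module(module, data.cond_b, data.cond_a)
    assert fwd_abs.delta == pytest.approx(rev_abs.delta, abs=1e-12)
    fwd = score_module(module, data.cond_a, data.cond_b, delta_mode="signed")
    rev = score_module(module, data.cond_b, data.cond_a, delta_mode="signed")
    assert fwd.delta == pytest.approx(-rev.delta, abs=1e-12)
    with pytest.raises(ValueError, match="delta_mode"):
        score_module(module, data.cond_a, data.cond_b, delta_mode="ratio")


def test_planted_module_exceeds_random_set_quantile(small_screen):
    """The decoupled module's ΔE beats the 95th percentile of size-matched
    random gene sets."""
    cohort, modules, data = small_screen
    planted_id = cohort.truth.planted_modules[0]
    planted = next(m for m in modules if m.set_id == planted_id)
    observed = score_module(planted, data.cond_a, data.cond_b,
                            workspaces=(data.workspace_a, data.workspace_b))
    rng = np.random.default_rng(7)
    null = []
    while len(null) < 50:
        rows = rng.choice(len(data.background_genes),
                          size=len(planted.proteins), replace=False)
        d = data.null_delta(rows, "absolute")
        if d is not None:
            null.append(d)
    assert observed.delta > np.quantile(null, 0.95)
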