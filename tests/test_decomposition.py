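"""Surprisal decomposition: SVD routes, invariants, reconstruction, residuals."""

import numpy as np
import pytest

from surprisal import (
    ExpressionMatrix,
    LogExpressionMatrix,
    decompose,
    log_transform,
    reconstruct,
    steady_state_residual,
)
from surprisal.decomposition import DecompositionError


def random_log_matrix(rng, m, t):
    names = tuple(f"g{i}" for i in range(m))
    conds = tuple(f"T{j}" for j in range(t))
    return LogExpressionMatrix(names, conds, rng.normal(5.0, 1.0, size=(m, t)))


class TestLogTransform:
    def test_analytic_values(self):
        x = ExpressionMatrix(
            ("a", "b"), ("T0",), np.array([[1.0], [np.e**2]])
        )
        y = log_transform(x)
        assert y.values[0, 0] == pytest.approx(0.0)
        assert y.values[1, 0] == pytest.approx(2.0)

    def test_matches_elementwise_oracle(self, rng):
        values = rng.uniform(0.5, 1e4, size=(5, 4))
        x = ExpressionMatrix(
            tuple(f"g{i}" for i in range(5)), tuple(f"T{j}" for j in range(4)), values
        )
        y = log_transform(x)
        oracle = np.array([[np.log(v) for v in row] for row in values])
        np.testing.assert_array_equal(y.values, oracle)


class TestDecompose:
    def test_rank_one_constant_matrix(self):
        y = LogExpressionMatrix(
            ("a", "b", "c"), ("T0", "T1"), np.full((3, 2), np.log(100.0))
        )
        d = decompose(y, "full_svd")
        assert d.omega[0] > 0
        assert d.omega[1] == pytest.approx(0.0, abs=1e-10)
        # higher patterns carry nothing
        assert np.max(np.abs(np.outer(d.G[:, 1], d.lam[1]))) < 1e-10
        rec = reconstruct(d, 1)
        np.testing.assert_allclose(rec.values, y.values, atol=1e-10)

    def test_two_by_two_against_brute_force_svd(self):
        values = np.array([[2.0, 0.0], [0.0, 1.0]])
        y = LogExpressionMatrix(("a", "b"), ("T0", "T1"), values)
        d = decompose(y, "full_svd")
        np.testing.assert_allclose(d.omega, [2.0, 1.0], atol=1e-12)
        # patterns align with coordinate axes up to the sign convention
        assert abs(d.G[0, 0]) == pytest.approx(1.0)
        assert abs(d.G[1, 1]) == pytest.approx(1.0)
        np.testing.assert_allclose(d.G @ d.lam, values, atol=1e-12)

    def test_four_conditions_give_four_by_four_multiplier_matrix(self, rng):
        y = random_log_matrix(rng, 50, 4)
        d = decompose(y)
        assert d.lam.shape == (4, 4)
        assert d.n_patterns == 4

    def test_more_conditions_than_genes_advises_transposition(self, rng):
        y = random_log_matrix(rng, 3, 5)
        with pytest.raises(DecompositionError, match="[Tt]ranspose"):
            decompose(y)

    def test_zero_matrix_returns_zero_decomposition(self):
        y = LogExpressionMatrix(("a", "b", "c"), ("T0", "T1"), np.zeros((3, 2)))
        for method in ("full_svd", "small_matrix"):
            d = decompose(y, method)
            np.testing.assert_array_equal(d.omega, [0.0, 0.0])
            np.testing.assert_allclose(d.G.T @ d.G, np.eye(2), atol=1e-10)

    @pytest.mark.parametrize("method", ["full_svd", "small_matrix"])
    def test_invariants_on_random_input(self, rng, method):
        y = random_log_matrix(rng, 200, 5)
        d = decompose(y, method)
        # orthonormal G columns
        np.testing.assert_allclose(d.G.T @ d.G, np.eye(5), atol=1e-10)
        # lam row orthogonality with squared singular values on the diagonal
        np.testing.assert_allclose(
            d.lam @ d.lam.T, np.diag(d.omega**2), atol=1e-8 * d.omega[0] ** 2
        )
        # omega sorted non-increasing
        assert np.all(np.diff(d.omega) <= 0)
        # full reconstruction
        scale = np.max(np.abs(y.values))
        assert np.max(np.abs(d.G @ d.lam - y.values)) < 1e-10 * scale

    def test_route_equivalence(self, rng):
        for _ in range(20):
            m = int(rng.integers(5, 80))
            t = int(rng.integers(2, min(m, 8) + 1))
            y = random_log_matrix(rng, m, t)
            a = decompose(y, "full_svd")
            b = decompose(y, "small_matrix")
            np.testing.assert_allclose(a.omega, b.omega, rtol=1e-8, atol=1e-8)
            np.testing.assert_allclose(a.G, b.G, atol=1e-7)
            np.testing.assert_allclose(a.lam, b.lam, atol=1e-7)

    def test_sign_convention_steady_state_negative(self, small_planted):
        x, _ = small_planted
        for method in ("full_svd", "small_matrix"):
            d = decompose(log_transform(x), method)
            # stable transcripts carry the lowest (negative) G_i0
            assert np.sum(d.G[:, 0]) < 0
            assert np.mean(d.G[:, 0] < 0) > 0.99
            # steady-state term reproduces positive log expression
            assert np.all(np.outer(d.G[:, 0], d.lam[0]) > 0)

    def test_effective_rank_bounded_by_conditions(self, rng):
        y = random_log_matrix(rng, 100, 4)
        d = decompose(y)
        assert d.effective_rank() <= 4
        # rank-2 input has effective rank 2 (direct SVD route: the Gram-matrix
        # route squares the condition number and blurs exact-zero detection)
        low = y.values[:, :2] @ rng.normal(size=(2, 4))
        y2 = LogExpressionMatrix(y.gene_names, y.condition_names, low)
        assert decompose(y2, "full_svd").effective_rank() == 2


class TestReconstruct:
    def test_full_rank_reproduces_input(self, rng):
        y = random_log_matrix(rng, 30, 4)
        d = decompose(y)
        rec = reconstruct(d, 4)
        assert np.max(np.abs(rec.values - y.values)) < 1e-10 * np.max(np.abs(y.values))

    def test_rank_one_truncation_obeys_eckart_young(self):
        values = np.array([[2.0, 0.0], [0.0, 1.0]])
        y = LogExpressionMatrix(("a", "b"), ("T0", "T1"), values)
        d = decompose(y, "full_svd")
        rec = reconstruct(d, 1)
        frob = np.linalg.norm(rec.values - values)
        assert frob == pytest.approx(d.omega[1], abs=1e-12)

    def test_k_out_of_range(self, rng):
        d = decompose(random_log_matrix(rng, 10, 3))
        for k in (0, 4):
            with pytest.raises(DecompositionError):
                reconstruct(d, k)

    def test_stable_gene_row_reproduced_by_steady_state_only(
        self, planted_decomposition, planted_default
    ):
        d, truth = planted_decomposition
        x, _ = planted_default
        rec1 = reconstruct(d, 1)
        logx = np.log(x.values)
        stable = list(truth.stable_genes)
        err = np.max(np.abs(rec1.values[stable] - logx[stable]))
        # within a few noise standard deviations
        assert err < 6 * truth.noise_sd


class TestSteadyStateResidual:
    def test_zero_for_exactly_steady_gene(self):
        # every gene proportional to the steady-state profile: rank 1
        rng = np.random.default_rng(0)
        g = rng.uniform(0.5, 1.5, size=20)
        lam = np.array([5.0, 5.1, 4.9, 5.0])
        y = LogExpressionMatrix(
            tuple(f"g{i}" for i in range(20)),
            tuple(f"T{j}" for j in range(4)),
            np.outer(g, lam),
        )
        res = steady_state_residual(decompose(y))
        assert np.max(res) < 1e-10

    def test_planted_deviating_residual_matches_truth(self, planted_decomposition):
        d, truth = planted_decomposition
        res = steady_state_residual(d)
        expected = np.max(
            np.abs(np.outer(truth.G_true[:, 1], truth.lam_true[1])), axis=1
        )
        dev = list(truth.deviating_genes)
        np.testing.assert_allclose(res[dev], expected[dev], atol=6 * truth.noise_sd)

    def test_planted_group_ordering(self, planted_decomposition):
        d, truth = planted_decomposition
        res = steady_state_residual(d)
        stable = list(truth.stable_genes)
        dev = list(truth.deviating_genes)
        assert res[stable].mean() < res[dev].mean()
        assert np.all(res >= 0)


class TestParameterRecovery:
    def test_planted_patterns_recovered(self, planted_decomposition):
        d, truth = planted_decomposition
        cos0 = abs(float(d.G[:, 0] @ truth.G_true[:, 0]))
        cos1 = abs(float(d.G[:, 1] @ truth.G_true[:, 1]))
        assert cos0 >= 0.99
        assert cos1 >= 0.99
        r = abs(np.corrcoef(d.lam[1], truth.lam_true[1])[0, 1])
        assert r >= 0.99

    def test_steady_state_dominates(self, planted_decomposition):
        d, _ = planted_decomposition
        assert np.all(d.omega[0] > d.omega[1:])


def test_serialization_round_trip(tmp_path, rng):
    y = random_log_matrix(rng, 25, 3)
    d = decompose(y)
    d.save(tmp_path)
    from surprisal import SurprisalDecomposition

    loaded = SurprisalDecomposition.load(tmp_path)
    assert loaded.gene_names == d.gene_names
    assert loaded.condition_names == d.condition_names
    np.testing.assert_allclose(loaded.G, d.G, atol=1e-12)
    np.testing.assert_allclose(loaded.lam, d.lam, atol=1e-12)
    np.testing.assert_allclose(loaded.omega, d.omega, atol=1e-12)
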