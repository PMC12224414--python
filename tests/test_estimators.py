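import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from rsldecode import (
    RSLDecoder,
    fit_ols,
    fit_regularized,
    growl_penalty,
    growl_weights,
    predict,
    prox_growl,
    prox_lasso,
)
from rsldecode.errors import RankDeficientError, RSLError

from _oracles import penalty_bruteforce, prox_objective, prox_reference


class TestWeights:
    def test_linear_decay_formula(self):
        assert np.allclose(growl_weights(3, 1.0, 2.0), [3.0, 2.0, 1.0])

    def test_omega_zero_is_constant_group_lasso_limit(self):
        assert np.allclose(growl_weights(5, 0.7, 0.0), 0.7)

    @given(st.integers(1, 50), st.floats(0, 5), st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_nonincreasing_nonnegative(self, m, lam, omega):
        w = growl_weights(m, lam, omega)
        assert np.all(np.diff(w) <= 1e-12) and np.all(w >= 0)

    def test_invalid_inputs(self):
        with pytest.raises(RSLError):
            growl_weights(0, 1, 1)
        with pytest.raises(RSLError):
            growl_weights(3, -1, 0)


class TestPenalty:
    def test_zero_matrix(self):
        assert growl_penalty(np.zeros((3, 2)), np.array([2.0, 1.0, 1.0])) == 0

    def test_largest_weight_pairs_with_largest_norm(self):
        beta = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]])
        assert growl_penalty(beta, np.array([2.0, 1.0, 1.0])) == pytest.approx(10.0)

    @given(
        hnp.arrays(float, (4, 2), elements=st.floats(-5, 5)),
        st.floats(0, 3), st.floats(0, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_max_over_pairings(self, beta, lam, omega):
        w = growl_weights(4, lam, omega)
        assert growl_penalty(beta, w) == pytest.approx(
            penalty_bruteforce(beta, w), abs=1e-9
        )


class TestProx:
    def test_group_soft_threshold_single_row(self):
        out = prox_growl(np.array([[3.0, 4.0]]), np.array([1.0]), step=1.0)
        assert np.allclose(out, [[2.4, 3.2]])

    def test_zero_weights_are_identity(self):
        V = np.random.default_rng(0).standard_normal((5, 3))
        assert np.allclose(prox_growl(V, np.zeros(5), 1.0), V)

    def test_hand_worked_pooling_example(self):
        """Two rows of norm 5 with weights (2, 1): norms pool at 3.5."""
        V = np.array([[3.0, 4.0], [5.0, 0.0]])
        out = prox_growl(V, np.array([2.0, 1.0]), step=1.0)
        assert np.allclose(out, [[2.1, 2.8], [3.5, 0.0]])
        assert np.allclose(np.linalg.norm(out, axis=1), 3.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_isotonic_reference_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m, r = int(rng.integers(1, 7)), int(rng.integers(1, 4))
        V = rng.standard_normal((m, r)) * 3
        w = growl_weights(m, rng.uniform(0, 2), rng.uniform(0, 2))
        step = rng.uniform(0.05, 2.0)
        ours = prox_growl(V, w, step)
        assert np.allclose(ours, prox_reference(V, w, step), atol=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_minimizes_prox_objective(self, seed):
        """The prox output beats random perturbations on the prox objective."""
        rng = np.random.default_rng(seed)
        m, r = int(rng.integers(1, 6)), int(rng.integers(1, 4))
        V = rng.standard_normal((m, r)) * 2
        w = growl_weights(m, rng.uniform(0, 1.5), rng.uniform(0, 1.5))
        step = rng.uniform(0.1, 1.5)
        B = prox_growl(V, w, step)
        f0 = prox_objective(B, V, w, step)
        for _ in range(20):
            pert = B + rng.standard_normal(B.shape) * rng.uniform(1e-4, 0.5)
            assert prox_objective(pert, V, w, step) >= f0 - 1e-9

    def test_lasso_prox_soft_thresholds(self):
        V = np.array([[0.5, -3.0]])
        assert np.allclose(prox_lasso(V, 1.0), [[0.0, -2.0]])
        assert np.allclose(prox_lasso(V, 0.0), V)

    def test_invalid_step(self):
        with pytest.raises(RSLError):
            prox_growl(np.ones((2, 2)), np.ones(2), step=0.0)


class TestOLS:
    def test_recovers_planted_coefficients(self, rng):
        X = rng.standard_normal((30, 5))
        beta_true = rng.standard_normal((5, 3))
        model = fit_ols(X, X @ beta_true)
        assert np.allclose(model.beta_raw_, beta_true, atol=1e-8)

    def test_orthonormal_design_closed_form(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((20, 6)))
        U = rng.standard_normal((20, 2))
        model = fit_ols(Q, U)
        assert np.allclose(model.beta_raw_, Q.T @ U, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((30, 5))
        U = rng.standard_normal((30, 3))
        model = fit_ols(X, U)
        expect = np.linalg.solve(X.T @ X, X.T @ U)
        assert np.allclose(model.beta_raw_, expect, atol=1e-8)
        resid = U - X @ model.beta_raw_
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_rank_deficiency_requires_opt_in(self, rng):
        X = rng.standard_normal((5, 10))
        U = rng.standard_normal((5, 2))
        with pytest.raises(RankDeficientError, match="infinitely many"):
            fit_ols(X, U)
        model = fit_ols(X, U, allow_singular=True)
        assert np.allclose(X @ model.beta_raw_, U, atol=1e-8)


class TestRegularizedFit:
    def test_alpha_zero_equals_ols(self, rng):
        X = rng.standard_normal((25, 6))
        U = rng.standard_normal((25, 2))
        m0 = fit_regularized(X, U, "growl", alpha=0.0)
        m1 = fit_ols(X, U)
        assert np.allclose(m0.beta_raw_, m1.beta_raw_, atol=1e-6)

    def test_huge_alpha_kills_every_row(self, rng):
        X = rng.standard_normal((25, 6))
        U = rng.standard_normal((25, 2))
        for family in ("growl", "lasso"):
            m = fit_regularized(X, U, family, alpha=1e4)
            assert np.all(m.beta_raw_ == 0)

    def test_row_support_monotone_in_alpha(self, rng):
        X = rng.standard_normal((40, 12))
        U = X[:, :3] @ rng.standard_normal((3, 3)) + 0.1 * rng.standard_normal((40, 3))
        sizes = []
        for alpha in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):
            m = fit_regularized(X, U, "growl", alpha=alpha, lam=1.0, omega=1.0, tol=1e-12)
            sizes.append(len(m.nonzero_rows()))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_objective_path_nonincreasing(self, rng):
        X = rng.standard_normal((30, 10))
        U = rng.standard_normal((30, 3))
        m = fit_regularized(X, U, "growl", alpha=0.05, lam=0.5, omega=0.5)
        path = np.asarray(m.objective_path_)
        assert np.all(np.diff(path) <= 1e-10)

    def test_growl_clusters_duplicates_where_lasso_splits(self, rng):
        """Near-duplicate predictors get near-identical coefficient rows under
        the ordered-weighted penalty but disjoint support under plain L1."""
        X = rng.standard_normal((60, 6))
        X[:, 1] = X[:, 0] + 0.01 * rng.standard_normal(60)
        U = np.column_stack(
            [X[:, 0] + 0.5 * X[:, 2], X[:, 0] - X[:, 2], 0.3 * X[:, 0] + X[:, 2]]
        )
        U += 0.05 * rng.standard_normal(U.shape)
        g = RSLDecoder("growl", alpha=0.05, lam=0.1, omega=2.0,
                       standardize=False, tol=1e-12).fit(X, U)
        l = RSLDecoder("lasso", alpha=0.05, standardize=False, tol=1e-12).fit(X, U)
        b0, b1 = g.beta_raw_[0], g.beta_raw_[1]
        cos = b0 @ b1 / (np.linalg.norm(b0) * np.linalg.norm(b1))
        assert cos > 0.95
        lasso_rows = np.abs(l.beta_raw_[:2]) > 0
        # L1 breaks the tie arbitrarily: the duplicates end up with different
        # support patterns instead of shared coefficients
        assert not np.array_equal(lasso_rows[0], lasso_rows[1])
        c0, c1 = l.beta_raw_[0], l.beta_raw_[1]
        lasso_cos = c0 @ c1 / max(np.linalg.norm(c0) * np.linalg.norm(c1), 1e-12)
        assert lasso_cos < cos

    def test_predict_applies_training_transform(self, rng):
        X = rng.standard_normal((30, 8)) * 7 + 3
        U = rng.standard_normal((30, 2))
        m = RSLDecoder("growl", alpha=0.01, lam=0.5, omega=0.5).fit(X, U)
        assert np.allclose(m.predict(X[:5]), predict(m, X[:5]))
        with pytest.raises(RSLError, match="columns"):
            m.predict(X[:, :4])

    def test_zero_input_row_predicts_zero_without_standardization(self, rng):
        X = rng.standard_normal((20, 5))
        U = rng.standard_normal((20, 2))
        m = fit_regularized(X, U, "lasso", alpha=0.01)
        assert np.allclose(m.predict(np.zeros((1, 5))), 0.0)

    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        est = RSLDecoder("growl", alpha=0.02, lam=0.3, omega=0.7)
        params = est.get_params()
        assert params["omega"] == 0.7
        est2 = clone(est).set_params(alpha=0.5)
        assert est2.alpha == 0.5
        X = rng.standard_normal((20, 4))
        U = rng.standard_normal((20, 2))
        est.fit(X, U)
        assert est.coef_.shape == (2, 4)
        assert est.beta_.shape == (4, 2)
        assert est.score(X, U) <= 1.0
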