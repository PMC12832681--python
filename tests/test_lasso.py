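"""Weighted-Lasso solver oracles, KKT certificates, transform-selection CV."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso as SkLasso

import fcexplain as fx
from fcexplain.lasso import (
    SUPPORT_TOL,
    WeightedLassoFit,
    kkt_violation,
    lambda_max,
    weighted_lasso_objective,
)

KKT_TOL = 1e-5


def soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def orthonormal_centered_design(n, p, rng):
    """Orthonormal columns that are also mean-centered (QR of a centered
    Gaussian matrix: the Q columns stay orthogonal to the ones vector)."""
    G = rng.normal(size=(n, p))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    return Q[:, :p]


class TestTransformPenalties:
    def test_phi_zero_is_plain_lasso(self):
        S = fx.PenaltyScores(values=np.array([0.2, 5.0, 1.0]))
        np.testing.assert_array_equal(fx.transform_penalties(S, 0), 1.0)

    def test_mean_one_rescale_arithmetic(self):
        W = fx.transform_penalties(np.array([2.0, 8.0]), 1)
        np.testing.assert_allclose(W, [0.4, 1.6])

    def test_constant_scores_fixed_point(self):
        for phi in range(6):
            W = fx.transform_penalties(np.full(7, 3.3), phi)
            np.testing.assert_allclose(W, 1.0, atol=1e-12)

    def test_relative_order_preserved_and_sharpened(self):
        S = np.array([0.5, 1.0, 2.0])
        w1 = fx.transform_penalties(S, 1)
        w3 = fx.transform_penalties(S, 3)
        assert w1[0] < w1[1] < w1[2]
        assert w3[0] / w3[2] < w1[0] / w1[2]  # larger phi -> stronger contrast

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            fx.transform_penalties(np.ones(3), -1)


class TestSolverOracles:
    def test_soft_threshold_oracle_orthonormal(self):
        """On orthonormal centered designs the solution is coordinatewise
        soft-thresholding, including per-feature weights."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = orthonormal_centered_design(30, 5, rng)
            y = rng.normal(size=30)
            W = rng.uniform(0.5, 2.0, size=5)
            lam = 0.1
            fit = fx.weighted_lasso_fit(X, y, lam, W, standardize=False)
            expected = soft(X.T @ (y - y.mean()), lam * W)
            np.testing.assert_allclose(fit.beta, expected, atol=1e-6)

    def test_brute_force_objective_oracle_p2(self):
        """Random p=2 instances: solver objective matches a refined dense
        grid search within 1e-6."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10, 2))
            y = rng.normal(size=10)
            W = rng.uniform(0.5, 2.0, size=2)
            lam = rng.uniform(0.5, 3.0)
            fit = fx.weighted_lasso_fit(X, y, lam, W, standardize=False)
            obj_fit = weighted_lasso_objective(X, y, fit.beta, fit.intercept, lam, W)
            obj_grid = _grid_min_objective(X, y, lam, W)
            assert obj_fit <= obj_grid + 1e-6

    def test_full_shrinkage_above_lambda_max(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.integers(0, 2, size=40).astype(float)
        W = rng.uniform(0.5, 2.0, size=8)
        lam = lambda_max(X, y, W) * 1.01
        fit = fx.weighted_lasso_fit(X, y, lam, W)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-12)
        assert fit.intercept == pytest.approx(y.mean())

    def test_matches_sklearn_plain_lasso(self):
        """W = 1 reproduces the reference Lasso (alpha = lam / n)."""
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p = 30, 6
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            lam = 2.0
            fit = fx.weighted_lasso_fit(X, y, lam, standardize=False, tol=1e-10)
            sk = SkLasso(alpha=lam / n, fit_intercept=True, tol=1e-12,
                         max_iter=100_000).fit(X, y)
            ours = weighted_lasso_objective(X, y, fit.beta, fit.intercept, lam,
                                            np.ones(p))
            theirs = weighted_lasso_objective(X, y, sk.coef_, sk.intercept_, lam,
                                              np.ones(p))
            assert abs(ours - theirs) < 1e-6

    def test_monotone_shrinkage_in_weight(self, rng):
        """Raising one feature's penalty weight weakly shrinks it
        (orthonormal design, where the effect is exact)."""
        X = orthonormal_centered_design(30, 4, rng)
        y = rng.normal(size=30)
        prev = np.inf
        for w0 in (0.5, 1.0, 2.0, 4.0):
            W = np.array([w0, 1.0, 1.0, 1.0])
            fit = fx.weighted_lasso_fit(X, y, 0.05, W, standardize=False)
            assert abs(fit.beta[0]) <= prev + 1e-12
            prev = abs(fit.beta[0])

    def test_kkt_certificate_random_instances(self, rng):
        for _ in range(10):
            X = rng.normal(size=(25, 12))
            y = rng.integers(0, 2, size=25).astype(float)
            W = rng.uniform(0.3, 3.0, size=12)
            lam = rng.uniform(0.1, 2.0) * lambda_max(X, y, W)
            fit = fx.weighted_lasso_fit(X, y, lam, W)
            assert fit.converged
            assert kkt_violation(X, y, fit) < KKT_TOL

    def test_nonfinite_input_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fx.weighted_lasso_fit(X, np.ones(4), 0.1)


def _grid_min_objective(X, y, lam, W, half_width=3.0, n_coarse=301, n_fine=201):
    """Two-stage dense grid minimizer over (beta1, beta2); the intercept is
    profiled out exactly (beta0 = mean(y - X beta))."""

    def objective_grid(b1, b2):
        B = np.stack(np.meshgrid(b1, b2, indexing="ij"), axis=-1)  # (g1,g2,2)
        pred = np.tensordot(B, X.T, axes=(2, 0))  # (g1,g2,n)
        b0 = (y - pred).mean(axis=-1, keepdims=True)
        resid = y - pred - b0
        pen = lam * (W[0] * np.abs(B[..., 0]) + W[1] * np.abs(B[..., 1]))
        return 0.5 * np.sum(resid**2, axis=-1) + pen

    b1 = np.linspace(-half_width, half_width, n_coarse)
    b2 = np.linspace(-half_width, half_width, n_coarse)
    obj = objective_grid(b1, b2)
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    # refine around the coarse argmin (include 0 exactly: the kink matters)
    step = b1[1] - b1[0]
    fine1 = np.unique(np.append(np.linspace(b1[i] - step, b1[i] + step, n_fine), 0.0))
    fine2 = np.unique(np.append(np.linspace(b2[j] - step, b2[j] + step, n_fine), 0.0))
    return float(objective_grid(fine1, fine2).min())


class TestSelectFeatures:
    def _fake_fit(self, beta_std):
        beta_std = np.asarray(beta_std, float)
        p = beta_std.size
        return WeightedLassoFit(
            beta=beta_std.copy(), intercept=0.0, lam=0.1, weights=np.ones(p),
            beta_std=beta_std, feature_mean=np.zeros(p), feature_scale=np.ones(p),
            n_iter=1, converged=True,
        )

    def test_magnitude_sort(self):
        assert fx.select_features(self._fake_fit([0.0, 0.5, -0.2, 0.0])) == [1, 2]

    def test_all_zero_warns_empty(self, caplog):
        assert fx.select_features(self._fake_fit([0.0, 0.0])) == []
        assert "empty support" in caplog.text

    def test_support_threshold(self):
        fit = self._fake_fit([SUPPORT_TOL / 2, 1.0])
        assert fx.select_features(fit) == [1]


class TestTransformSelectionCV:
    def test_uniform_scores_columns_equal_tie_to_zero(self, small_dataset):
        s = fx.generate_penalty_scores(
            small_dataset.edge_map, (0,), "uniform", 0
        )
        sel = fx.select_transform_cv(
            small_dataset.X, small_dataset.Y, s, phi_grid=(0, 1, 2), seed=0,
            n_lambda=8,
        )
        for i in range(1, 3):
            np.testing.assert_allclose(
                sel.cv_losses[i], sel.cv_losses[0], atol=1e-10
            )
        assert sel.phi_star == 0

    def test_guard_selected_loss_never_above_plain_lasso(self, small_dataset, small_spec):
        for mode in ("informative", "misleading"):
            s = fx.generate_penalty_scores(
                small_dataset.edge_map, small_spec.signal_edges, mode, 1
            )
            sel = fx.select_transform_cv(
                small_dataset.X, small_dataset.Y, s, phi_grid=(0, 1, 2, 3),
                seed=1, n_lambda=10,
            )
            assert sel.selected_loss <= sel.baseline_loss + 1e-12

    def test_informative_scores_beat_plain_lasso_here(self, small_dataset, small_spec):
        s = fx.generate_penalty_scores(
            small_dataset.edge_map, small_spec.signal_edges, "informative", 1
        )
        sel = fx.select_transform_cv(
            small_dataset.X, small_dataset.Y, s, seed=1
        )
        assert sel.phi_star > 0
        assert sel.selected_loss < sel.baseline_loss

    def test_phi_grid_must_contain_zero(self, small_dataset):
        with pytest.raises(ValueError, match="0"):
            fx.select_transform_cv(
                small_dataset.X, small_dataset.Y,
                np.ones(small_dataset.p), phi_grid=(1, 2),
            )

    def test_single_class_fold_reported(self, small_dataset):
        with pytest.raises(ValueError, match="class"):
            fx.select_transform_cv(
                small_dataset.X, np.ones(small_dataset.n),
                np.ones(small_dataset.p),
            )

    def test_fold_assignment_deterministic(self, small_dataset):
        s = np.ones(small_dataset.p)
        a = fx.select_transform_cv(small_dataset.X, small_dataset.Y, s,
                                   phi_grid=(0,), seed=5, n_lambda=5)
        b = fx.select_transform_cv(small_dataset.X, small_dataset.Y, s,
                                   phi_grid=(0,), seed=5, n_lambda=5)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
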