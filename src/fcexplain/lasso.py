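"""Knowledge-weighted Lasso with cross-validated penalty-transform selection.

The plain Lasso

    min_beta  1/2 * sum_i (y_i - beta0 - x_i' beta)^2 + lam * sum_j |beta_j|

penalizes every feature equally.  Here each feature j carries a strictly
positive penalty factor omega_j (small = prior evidence the feature
matters), giving the weighted objective

    1/2 * sum_i (y_i - beta0 - x_i' beta)^2 + lam * sum_j omega_j |beta_j|

The factors come from an external knowledge source as raw scores
S = (s_1..s_p).  How literally to trust them is decided by the data: the
power-transform family  W = S**phi, phi in {0, 1, ..., phi_max}  spans
"ignore the scores" (phi = 0, plain Lasso) to "rely on them heavily", and
k-fold cross-validation picks the (phi, lam) pair with the lowest
validation loss.  Because phi = 0 is always in the family, the selected
cross-validation loss can never exceed the plain-Lasso optimum — a built-in
guard against unreliable scores.

Labels enter the regression as 0/1 reals; classification proper is
delegated to the downstream margin classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .llm import PenaltyScores

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100_000
SUPPORT_TOL = 1e-8


def _cd_sweeps_py(Xs, yc, b, r, z, thresh, tol, max_iter):
    """Cyclic coordinate-descent sweeps (reference implementation)."""
    n, p = Xs.shape
    n_iter = 0
    converged = False
    for sweep in range(max_iter):
        n_iter = sweep + 1
        max_delta = 0.0
        for j in range(p):
            if z[j] == 0.0:
                continue
            bj = b[j]
            cj = Xs[:, j] @ r + z[j] * bj
            t = thresh[j]
            if cj > t:
                new = (cj - t) / z[j]
            elif cj < -t:
                new = (cj + t) / z[j]
            else:
                new = 0.0
            if new != bj:
                r += Xs[:, j] * (bj - new)
                b[j] = new
                delta = abs(new - bj)
                if delta > max_delta:
                    max_delta = delta
        if max_delta < tol:
            converged = True
            break
    return n_iter, converged


def _make_compiled_sweeps():
    from numba import njit

    @njit(cache=True)
    def _cd_sweeps_nb(Xs, yc, b, r, z, thresh, tol, max_iter):
        n, p = Xs.shape
        n_iter = 0
        converged = False
        for sweep in range(max_iter):
            n_iter = sweep + 1
            max_delta = 0.0
            for j in range(p):
                if z[j] == 0.0:
                    continue
                bj = b[j]
                cj = z[j] * bj
                for i in range(n):
                    cj += Xs[i, j] * r[i]
                t = thresh[j]
                if cj > t:
                    new = (cj - t) / z[j]
                elif cj < -t:
                    new = (cj + t) / z[j]
                else:
                    new = 0.0
                if new != bj:
                    d = bj - new
                    for i in range(n):
                        r[i] += Xs[i, j] * d
                    b[j] = new
                    if abs(new - bj) > max_delta:
                        max_delta = abs(new - bj)
            if max_delta < tol:
                converged = True
                break
        return n_iter, converged

    return _cd_sweeps_nb


try:  # same algorithm, compiled; the numpy loop is the fallback
    _cd_sweeps = _make_compiled_sweeps()
except ImportError:  # pragma: no cover
    _cd_sweeps = _cd_sweeps_py


def transform_penalties(S: PenaltyScores | np.ndarray, phi: int) -> np.ndarray:
    """Power-transform raw scores into penalty weights: W_j = s_j**phi.

    The result is rescaled to mean 1 so that lambda grids stay comparable
    across phi (relative penalization is unchanged by the rescale).
    phi = 0 returns exactly all-ones — the plain-Lasso penalty.
    """
    values = S.values if isinstance(S, PenaltyScores) else np.asarray(S, float)
    if phi < 0 or int(phi) != phi:
        raise ValueError("phi must be a nonnegative integer")
    if phi == 0:
        return np.ones_like(values)
    W = values ** phi
    return W / W.mean()


@dataclass
class WeightedLassoFit:
    """A converged weighted-Lasso solution.

    beta/intercept are on the original feature scale; beta_std holds the
    standardized-scale coefficients on which the penalty acted and on which
    the support threshold is applied.
    """

    beta: np.ndarray
    intercept: float
    lam: float
    weights: np.ndarray
    beta_std: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    n_iter: int
    converged: bool
    support_tol: float = SUPPORT_TOL

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.beta_std) > self.support_tol)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.beta


def _standardize(X: np.ndarray, scale_features: bool = True):
    """Center columns (always — makes the unpenalized intercept separable)
    and optionally rescale them to unit standard deviation."""
    mean = X.mean(axis=0)
    if scale_features:
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
    else:
        scale = np.ones(X.shape[1])
    return (X - mean) / scale, mean, scale


def lambda_max(X: np.ndarray, Y: np.ndarray, W: np.ndarray) -> float:
    """Smallest lambda at which every coefficient is shrunk to zero."""
    Xs, _, _ = _standardize(np.asarray(X, float))
    yc = np.asarray(Y, float) - np.mean(Y)
    return float(np.max(np.abs(Xs.T @ yc) / W))


def weighted_lasso_fit(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    W: np.ndarray | None = None,
    *,
    standardize: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    beta_init: np.ndarray | None = None,
    support_tol: float = SUPPORT_TOL,
) -> WeightedLassoFit:
    """Cyclic coordinate descent on the weighted-Lasso objective.

    Features are centered and unit-scaled internally (the penalty acts on
    standardized coefficients, as is conventional); coefficients are
    reported back on the original scale and the intercept is unpenalized.
    Convergence: max standardized-coefficient change in a sweep < tol.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in X or Y")
    if X.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X must be n x p with one label per row")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n, p = X.shape
    W = np.ones(p) if W is None else np.asarray(W, dtype=float)
    if W.shape != (p,) or np.any(W <= 0):
        raise ValueError("weights must be a length-p strictly positive vector")

    # Columns are always centered so the unpenalized intercept decouples
    # from the coordinate updates; unit-scaling is optional.
    Xs, mean, scale = _standardize(X, scale_features=standardize)
    ybar = Y.mean()
    yc = Y - ybar

    b = np.zeros(p) if beta_init is None else np.array(beta_init, dtype=float)
    z = np.einsum("ij,ij->j", Xs, Xs)  # per-column squared norms
    Xs = np.asfortranarray(Xs)  # column-contiguous access in the sweeps
    r = yc - Xs @ b
    thresh = lam * W

    n_iter, converged = _cd_sweeps(Xs, yc, b, r, z, thresh, tol, max_iter)
    if not converged:
        logger.warning("coordinate descent hit max_iter=%d without converging", max_iter)

    beta = b / scale
    intercept = ybar - float(mean @ beta)
    return WeightedLassoFit(
        beta=beta, intercept=intercept, lam=lam, weights=W, beta_std=b.copy(),
        feature_mean=mean, feature_scale=scale, n_iter=n_iter,
        converged=converged, support_tol=support_tol,
    )


def weighted_lasso_objective(
    X: np.ndarray, Y: np.ndarray, beta: np.ndarray, intercept: float,
    lam: float, W: np.ndarray,
) -> float:
    """1/2 * sum (y - beta0 - x'beta)^2 + lam * sum W_j |beta_j|.

    Evaluated on original-scale coefficients; for fits run with
    ``standardize=False`` this is exactly the quantity the solver minimizes.
    """
    resid = np.asarray(Y, float) - intercept - np.asarray(X, float) @ beta
    return float(0.5 * resid @ resid + lam * np.sum(W * np.abs(beta)))


def kkt_violation(X: np.ndarray, Y: np.ndarray, fit: WeightedLassoFit) -> float:
    """Largest violation of the weighted-Lasso stationarity conditions.

    On the internal standardized problem with gradient g = Xs'(yc - Xs b):
    |g_j| <= lam * W_j for zero coefficients and g_j = lam * W_j * sign(b_j)
    for nonzero ones.  Returns the max absolute slack; a converged fit
    should be near 0.
    """
    X = np.asarray(X, float)
    Xs = (X - fit.feature_mean) / fit.feature_scale
    yc = np.asarray(Y, float) - np.mean(Y)
    g = Xs.T @ (yc - Xs @ fit.beta_std)
    lamw = fit.lam * fit.weights
    zero = np.abs(fit.beta_std) <= fit.support_tol
    viol_zero = np.maximum(np.abs(g[zero]) - lamw[zero], 0.0)
    viol_nz = np.abs(g[~zero] - lamw[~zero] * np.sign(fit.beta_std[~zero]))
    parts = [v for v in (viol_zero, viol_nz) if v.size]
    return float(max(v.max() for v in parts)) if parts else 0.0


def select_features(fit: WeightedLassoFit) -> list[int]:
    """Support of the fit, sorted by standardized |beta_j| descending."""
    idx = fit.support
    if idx.size == 0:
        logger.warning("empty support: no features selected at lam=%g", fit.lam)
        return []
    order = np.argsort(-np.abs(fit.beta_std[idx]), kind="stable")
    return [int(j) for j in idx[order]]


# ---------------------------------------------------------------------------
# Cross-validated transform selection


@dataclass
class TransformSelection:
    """Result of the joint (phi, lambda) cross-validation."""

    phi_grid: tuple[int, ...]
    lam_grids: np.ndarray  # (n_phi, n_lambda), descending per row
    cv_losses: np.ndarray  # (n_phi, n_lambda) mean validation losses
    phi_star: int
    lam_star: float
    final_weights: np.ndarray
    folds: int
    fold_assignment: np.ndarray

    @property
    def baseline_loss(self) -> float:
        """Best cross-validation loss attainable at phi = 0 (plain Lasso)."""
        i0 = self.phi_grid.index(0)
        return float(self.cv_losses[i0].min())

    @property
    def selected_loss(self) -> float:
        i = self.phi_grid.index(self.phi_star)
        j = int(np.flatnonzero(self.lam_grids[i] == self.lam_star)[0])
        return float(self.cv_losses[i, j])


def _mse_loss(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def _misclass_loss(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred >= 0.5).astype(int) != y))


def select_transform_cv(
    X: np.ndarray,
    Y: np.ndarray,
    S: PenaltyScores | np.ndarray,
    phi_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 5),
    k: int = 5,
    seed: int = 0,
    n_lambda: int = 20,
    lam_min_ratio: float = 1e-3,
    loss: str = "mse",
) -> TransformSelection:
    """Jointly select the transform exponent phi and penalty level lambda.

    For every fold and every (phi, lambda): fit the weighted Lasso on the
    training folds with weights S**phi (mean-1 rescaled), score the linear
    predictor on the validation fold.  The (phi, lambda) minimizing the
    mean validation loss wins; ties break to the smallest phi, then the
    largest lambda (least score dependence, sparsest model).  Because
    phi = 0 is in the grid, the selected loss never exceeds the best
    plain-Lasso loss.

    The lambda grid is per-phi: n_lambda log-spaced values from that
    phi's full-data lambda_max down lam_min_ratio decades.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 folds")
    phi_grid = tuple(int(f) for f in phi_grid)
    if 0 not in phi_grid:
        raise ValueError("phi_grid must contain 0 (the plain-Lasso guard)")
    classes, counts = np.unique(Y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation requires both classes present")
    if counts.min() < k:
        raise ValueError(
            f"stratification failure: minority class has {counts.min()} subjects "
            f"for k={k} folds"
        )
    loss_fn = {"mse": _mse_loss, "misclassification": _misclass_loss}[loss]

    weights_by_phi = [transform_penalties(S, phi) for phi in phi_grid]
    lam_grids = np.empty((len(phi_grid), n_lambda))
    for i, W in enumerate(weights_by_phi):
        lmax = lambda_max(X, Y, W)
        lam_grids[i] = np.geomspace(lmax, lmax * lam_min_ratio, n_lambda)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.empty(len(Y), dtype=int)
    losses = np.zeros((k, len(phi_grid), n_lambda))
    for fold, (tr, va) in enumerate(skf.split(X, Y)):
        fold_assignment[va] = fold
        Xtr, Ytr, Xva, Yva = X[tr], Y[tr], X[va], Y[va]
        for i, W in enumerate(weights_by_phi):
            beta_init = None
            for jl, lam in enumerate(lam_grids[i]):  # descending: warm starts
                fit = weighted_lasso_fit(Xtr, Ytr, lam, W, beta_init=beta_init)
                beta_init = fit.beta_std
                losses[fold, i, jl] = loss_fn(fit.predict(Xva), Yva)
    cv_losses = losses.mean(axis=0)

    # argmin with ties to smallest phi then largest lambda: scan phi
    # ascending, lambda descending (grid rows are already descending).
    best = (np.inf, 0, 0)
    for i in range(len(phi_grid)):
        for jl in range(n_lambda):
            if cv_losses[i, jl] < best[0]:
                best = (cv_losses[i, jl], i, jl)
    _, i_star, j_star = best
    phi_star = phi_grid[i_star]
    lam_star = float(lam_grids[i_star, j_star])

    sel = TransformSelection(
        phi_grid=phi_grid, lam_grids=lam_grids, cv_losses=cv_losses,
        phi_star=phi_star, lam_star=lam_star,
        final_weights=weights_by_phi[i_star], folds=k,
        fold_assignment=fold_assignment,
    )
    # The guard is structural; assert it on every run.
    assert sel.selected_loss <= sel.baseline_loss + 1e-12
    if phi_star == 0:
        logger.info("guard active: plain-Lasso weights selected (phi*=0)")
    return sel


def fit_selected(
    X: np.ndarray, Y: np.ndarray, selection: TransformSelection
) -> WeightedLassoFit:
    """Refit on the full data at the chosen (phi*, lambda*)."""
    return weighted_lasso_fit(
        X, Y, selection.lam_star, selection.final_weights
    )
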