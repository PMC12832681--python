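"""Diverse counterfactual generation over a trained margin classifier.

For a subject with selected-edge vector m (typically a patient the model
predicts as class 0), the engine searches for L alternative vectors
x^1..x^L that the classifier assigns to the target class (by default 1,
normal control), while staying close to m and mutually diverse:

    minimize  (1/L) * sum_l  max(0, 1 - z * logit(x^l))        [validity]
            + gamma1 * (1/L) * sum_l dist(x^l, m)              [proximity]
            - gamma2 * det(K)                                  [diversity]

where z = +1 when the target label is 1 and -1 when it is 0, dist is the
MAD-normalized mean absolute feature difference, and K is the similarity
kernel K[u,v] = 1 / (1 + dist(x^u, x^v)) with a small seeded jitter on the
diagonal to keep the determinant well conditioned.  Optimization is
projected (sub)gradient descent with backtracking, candidates clipped to
the FC value box (-1, 1) every step.

A greedy post-hoc sparsifier can restore needlessly changed edges to their
original values, yielding counterfactuals that touch only one or two
connections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import MarginClassifier

logger = logging.getLogger(__name__)

MAD_FLOOR = 1e-3
DIFF_TOL = 1e-9


@dataclass
class MADVector:
    """Per-feature median absolute deviation of the training set."""

    values: np.ndarray
    floor: float = MAD_FLOOR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def compute_mads(Xq_train: np.ndarray, floor: float = MAD_FLOOR) -> MADVector:
    """MAD_a = median(|x_a - median(x_a)|) per feature, floored.

    Constant features have zero MAD; they are replaced by `floor` with a
    warning so normalized distances stay finite.
    """
    Xq_train = np.atleast_2d(np.asarray(Xq_train, float))
    if Xq_train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to compute MADs")
    med = np.median(Xq_train, axis=0)
    mads = np.median(np.abs(Xq_train - med), axis=0)
    degenerate = mads < floor
    if degenerate.any():
        logger.warning(
            "%d feature(s) with MAD below %g floored", int(degenerate.sum()), floor
        )
        mads = np.where(degenerate, floor, mads)
    return MADVector(values=mads, floor=floor)


def hinge_loss(logit: float | np.ndarray, target: int) -> float | np.ndarray:
    """max(0, 1 - z * logit), z = +1 for target 1, -1 for target 0."""
    z = 1.0 if target == 1 else -1.0
    return np.maximum(0.0, 1.0 - z * np.asarray(logit, float))


def mad_distance(x: np.ndarray, m: np.ndarray, mads: MADVector) -> float:
    """Mean over features of |x_a - m_a| / MAD_a; symmetric, zero iff x = m."""
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    if x.shape != m.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {m.shape}")
    return float(np.mean(np.abs(x - m) / mads.values))


def _kernel(candidates: np.ndarray, mads: MADVector,
            jitter: np.ndarray | None = None) -> np.ndarray:
    L = candidates.shape[0]
    K = np.empty((L, L))
    for u in range(L):
        K[u, u] = 1.0
        for v in range(u + 1, L):
            d = mad_distance(candidates[u], candidates[v], mads)
            K[u, v] = K[v, u] = 1.0 / (1.0 + d)
    if jitter is not None:
        K[np.diag_indices(L)] += jitter
    return K


def diversity_det(
    candidates: np.ndarray,
    mads: MADVector,
    jitter_scale: float = 0.0,
    seed: int = 0,
) -> float:
    """Determinant of the similarity kernel over candidates.

    Near 0 for duplicated candidates, approaching 1 as pairwise distances
    grow.  jitter_scale > 0 adds a seeded uniform perturbation in
    [0, jitter_scale] to each diagonal entry before taking the determinant.
    """
    candidates = np.atleast_2d(np.asarray(candidates, float))
    jitter = None
    if jitter_scale > 0:
        jitter = np.random.default_rng(seed).uniform(
            0.0, jitter_scale, size=candidates.shape[0]
        )
    return float(np.linalg.det(_kernel(candidates, mads, jitter)))


@dataclass
class CFConfig:
    """Counterfactual search settings (defaults: L=5, gamma1=0.5, gamma2=1)."""

    L: int = 5
    gamma1: float = 0.5
    gamma2: float = 1.0
    target_label: int = 1
    learning_rate: float = 0.05
    max_iters: int = 2000
    n_restarts: int = 3
    seed: int = 0
    bounds: tuple[float, float] = (-1.0, 1.0)
    jitter_scale: float = 1e-4
    init_sd: float = 0.05
    sparsify: bool = False

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma weights must be >= 0")
        if self.target_label not in (0, 1):
            raise ValueError("target_label must be 0 or 1")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("invalid box bounds")


@dataclass
class CounterfactualSet:
    """L candidate vectors for one subject, with validity bookkeeping."""

    original: np.ndarray
    candidates: np.ndarray  # (L, q)
    validity: np.ndarray  # (L,) bool: prediction == target_label
    target_label: int
    objective_trace: list[float]
    mads: MADVector

    @property
    def n_valid(self) -> int:
        return int(self.validity.sum())

    def diffs(self, candidate: int) -> list[tuple[int, float, float]]:
        """(feature index, original, new) for every changed feature,
        sorted by |delta|/MAD descending."""
        x = self.candidates[candidate]
        idx = np.flatnonzero(np.abs(x - self.original) > DIFF_TOL)
        scaled = np.abs(x[idx] - self.original[idx]) / self.mads.values[idx]
        order = idx[np.argsort(-scaled, kind="stable")]
        return [(int(j), float(self.original[j]), float(x[j])) for j in order]


def _objective_and_grad(
    Xc: np.ndarray,
    m: np.ndarray,
    model: MarginClassifier,
    config: CFConfig,
    mads: MADVector,
    jitter: np.ndarray,
):
    L, q = Xc.shape
    z = 1.0 if config.target_label == 1 else -1.0
    w = model.coef
    logits = model.logit(Xc)
    grad = np.zeros_like(Xc)

    # hinge term
    margins = 1.0 - z * logits
    active = margins > 0
    obj = float(np.sum(np.maximum(margins, 0.0))) / L
    grad[active] += (-z / L) * w

    # proximity term
    inv_mad = 1.0 / mads.values
    if config.gamma1 > 0:
        diffs = Xc - m
        obj += config.gamma1 * float(np.sum(np.abs(diffs) * inv_mad)) / (L * q)
        grad += config.gamma1 / (L * q) * np.sign(diffs) * inv_mad

    # diversity term (only defined for L >= 2; det == 1 + jitter for L == 1)
    if config.gamma2 > 0 and L >= 2:
        K = _kernel(Xc, mads, jitter)
        detK = float(np.linalg.det(K))
        obj -= config.gamma2 * detK
        # adj(K) = det(K) * inv(K) for invertible K (jitter keeps it so)
        try:
            adj = detK * np.linalg.inv(K)
        except np.linalg.LinAlgError:
            adj = np.zeros_like(K)
        for u in range(L):
            for v in range(L):
                if u == v:
                    continue
                # jitter is diagonal-only, so K[u,v] = 1/(1+d) exactly
                d = 1.0 / K[u, v] - 1.0
                dK_dd = -1.0 / (1.0 + d) ** 2
                sg = np.sign(Xc[u] - Xc[v]) * inv_mad / q
                # entries (u,v) and (v,u) both move with x_u: factor 2
                grad[u] += -config.gamma2 * 2.0 * adj[u, v] * dK_dd * sg
    elif config.gamma2 > 0 and L == 1:
        obj -= config.gamma2 * (1.0 + float(jitter[0]))
    return obj, grad


def generate_counterfactuals(
    model: MarginClassifier,
    m: np.ndarray,
    config: CFConfig | None = None,
    mads: MADVector | None = None,
    Xq_train: np.ndarray | None = None,
) -> CounterfactualSet:
    """Jointly optimize L counterfactual candidates for one subject.

    Projected subgradient descent with backtracking from seeded near-m
    initializations; the best of n_restarts runs (most valid candidates,
    then lowest objective) is returned.  Invalid candidates are flagged,
    never dropped.  Deterministic under a fixed config seed.
    """
    config = config or CFConfig()
    m = np.asarray(m, float).ravel()
    if mads is None:
        if Xq_train is None:
            raise ValueError("provide either mads or Xq_train")
        mads = compute_mads(Xq_train)
    lo, hi = config.bounds
    if np.any(m < lo) or np.any(m > hi):
        raise ValueError("original vector lies outside the configured bounds")
    rng = np.random.default_rng(config.seed)
    jitter = rng.uniform(0.0, config.jitter_scale, size=config.L)

    best: tuple[int, float, np.ndarray, list[float]] | None = None
    for restart in range(config.n_restarts):
        Xc = np.clip(
            m + rng.normal(scale=config.init_sd, size=(config.L, m.size)), lo, hi
        )
        lr = config.learning_rate
        obj, grad = _objective_and_grad(Xc, m, model, config, mads, jitter)
        trace = [obj]
        for _ in range(config.max_iters):
            stepped = False
            for _bt in range(20):
                Xn = np.clip(Xc - lr * grad, lo, hi)
                obj_n, grad_n = _objective_and_grad(Xn, m, model, config, mads, jitter)
                if obj_n <= obj - 1e-12:
                    Xc, obj, grad = Xn, obj_n, grad_n
                    trace.append(obj)
                    stepped = True
                    lr = min(lr * 1.2, config.learning_rate)
                    break
                lr *= 0.5
            if not stepped:
                break  # no descent direction at line-search tolerance
        preds = model.predict(Xc)
        n_valid = int(np.sum(preds == config.target_label))
        key = (n_valid, -obj)
        if best is None or key > (best[0], -best[1]):
            best = (n_valid, obj, Xc, trace)
    assert best is not None
    n_valid, obj, Xc, trace = best
    validity = model.predict(Xc) == config.target_label
    if n_valid == 0:
        logger.warning(
            "no valid counterfactual after %d restarts; best logits: %s",
            config.n_restarts, np.round(model.logit(Xc), 4),
        )
    cf = CounterfactualSet(
        original=m, candidates=Xc, validity=validity,
        target_label=config.target_label, objective_trace=trace, mads=mads,
    )
    if config.sparsify:
        cf = sparsify(cf, model)
    return cf


def sparsify(cf_set: CounterfactualSet, model: MarginClassifier) -> CounterfactualSet:
    """Greedily restore features to their original values.

    Per valid candidate, changed features are tried in ascending |delta|/MAD
    order; a restore is kept only if the prediction stays at the target
    label.  Never invalidates a candidate; weakly decreases the number of
    changed edges.  Invalid candidates are left untouched.
    """
    target = cf_set.target_label
    out = cf_set.candidates.copy()
    for l in range(out.shape[0]):
        if not cf_set.validity[l]:
            continue
        x = out[l].copy()
        changed = np.flatnonzero(np.abs(x - cf_set.original) > DIFF_TOL)
        scaled = np.abs(x[changed] - cf_set.original[changed]) / cf_set.mads.values[changed]
        for j in changed[np.argsort(scaled, kind="stable")]:
            trial = x.copy()
            trial[j] = cf_set.original[j]
            if model.predict(trial)[0] == target:
                x = trial
        out[l] = x
    validity = model.predict(out) == target
    assert np.all(validity[cf_set.validity]), "sparsify must not invalidate"
    return replace(cf_set, candidates=out, validity=validity)


def diff_report(cf_set: CounterfactualSet, edge_names: tuple[str, ...] | list[str]) -> str:
    """Human-readable per-candidate edge changes, largest normalized first."""
    edge_names = list(edge_names)
    lines: list[str] = []
    for l in range(cf_set.candidates.shape[0]):
        flag = "valid" if cf_set.validity[l] else "INVALID"
        lines.append(f"Counterfactual {l + 1} ({flag}):")
        diffs = cf_set.diffs(l)
        if not diffs:
            lines.append("  (no change)")
            continue
        for j, before, after in diffs:
            direction = "increase" if after > before else "decrease"
            lines.append(
                f"  {edge_names[j]}: {direction} from {before:+.3f} to {after:+.3f} "
                f"(delta {after - before:+.3f})"
            )
    return "\n".join(lines)
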