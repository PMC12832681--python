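"""Margin classification of selected FC edges and evaluation protocols.

A linear support-vector machine is trained on the reduced edge matrix
X' (n x q) that survives feature selection.  Linearity matters beyond
simplicity: the counterfactual engine needs the classifier's *unscaled*
decision value (the logit) to be an affine, differentiable function of the
inputs.

Label and metric conventions
----------------------------
Positives are the normal controls (label 1); patients are label 0.  Hence
SEN here is the true-positive rate *on controls* and SPE the true-negative
rate on patients — the reverse of many clinical papers, so it is stated
prominently.  ACC/SEN/SPE are reported as percentages.

Protocols: stratified k-fold (selection and training strictly inside each
training split — no leakage) and leave-one-dataset-out (train pooled on
all sites but one, test on the held-out site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC
from sklearn.model_selection import StratifiedKFold

from .dataset import FCDataset
from .lasso import fit_selected, select_features, select_transform_cv
from .llm import PenaltyScores

logger = logging.getLogger(__name__)


@dataclass
class MarginClassifier:
    """A fitted linear max-margin separator; predict 1 iff logit >= 0."""

    coef: np.ndarray
    intercept: float
    C: float = 1.0
    feature_indices: tuple[int, ...] | None = None  # columns of the full X

    def logit(self, Xq: np.ndarray) -> np.ndarray:
        """Unscaled decision value, affine in the inputs."""
        Xq = np.atleast_2d(np.asarray(Xq, float))
        return Xq @ self.coef + self.intercept

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        return (self.logit(Xq) >= 0).astype(int)


def train_margin_classifier(
    Xq: np.ndarray,
    Y: np.ndarray,
    C: float = 1.0,
    feature_indices: tuple[int, ...] | None = None,
) -> MarginClassifier:
    """Fit a linear SVM on the selected-edge matrix.

    Deterministic given (Xq, Y, C).  Rejects single-class input.
    """
    Xq = np.atleast_2d(np.asarray(Xq, float))
    Y = np.asarray(Y, int)
    if len(np.unique(Y)) < 2:
        raise ValueError("training data contains a single class")
    if Xq.shape[1] < 1:
        raise ValueError("need at least one feature")
    svc = SVC(kernel="linear", C=C)
    svc.fit(Xq, Y)
    return MarginClassifier(
        coef=svc.coef_.ravel().copy(), intercept=float(svc.intercept_[0]),
        C=C, feature_indices=tuple(feature_indices) if feature_indices else None,
    )


@dataclass
class ConfusionMetrics:
    """Counts and percentage metrics; positives = normal controls (label 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def acc(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def sen(self) -> float:
        denom = self.tp + self.fn
        if denom == 0:
            logger.warning("no positive subjects in truth: SEN undefined")
            return float("nan")
        return 100.0 * self.tp / denom

    @property
    def spe(self) -> float:
        denom = self.tn + self.fp
        if denom == 0:
            logger.warning("no negative subjects in truth: SPE undefined")
            return float("nan")
        return 100.0 * self.tn / denom

    def __str__(self) -> str:
        return (
            f"ACC {self.acc:.2f}%  SEN {self.sen:.2f}%  SPE {self.spe:.2f}%  "
            f"(TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn})"
        )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMetrics:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    return ConfusionMetrics(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def evaluate(model: MarginClassifier, Xq: np.ndarray, Y: np.ndarray) -> ConfusionMetrics:
    """Confusion counts and ACC/SEN/SPE of the model on (Xq, Y)."""
    return confusion_from_predictions(Y, model.predict(Xq))


# ---------------------------------------------------------------------------
# Protocols


@dataclass
class PipelineConfig:
    """Selection + classification settings shared by the protocols."""

    phi_grid: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    n_lambda: int = 20
    inner_folds: int = 5
    svm_C: float = 1.0
    cv_loss: str = "mse"


@dataclass
class FoldResult:
    metrics: ConfusionMetrics
    selected: list[int]
    phi_star: int
    lam_star: float
    train_indices: np.ndarray  # provenance for the no-leakage audit


def _select_and_train(
    X: np.ndarray, Y: np.ndarray, scores: PenaltyScores, config: PipelineConfig,
    seed: int,
):
    """Feature selection + SVM training on one training split."""
    sel = select_transform_cv(
        X, Y, scores, phi_grid=config.phi_grid, k=config.inner_folds,
        seed=seed, n_lambda=config.n_lambda, loss=config.cv_loss,
    )
    fit = fit_selected(X, Y, sel)
    selected = select_features(fit)
    if not selected:
        # Empty support is reported, then rescued with the single best
        # marginal edge so the protocol can still produce a classifier.
        corr = np.abs((X - X.mean(0)).T @ (Y - Y.mean()))
        selected = [int(np.argmax(corr))]
        logger.warning(
            "empty Lasso support; falling back to top marginal edge %d", selected[0]
        )
    model = train_margin_classifier(
        X[:, selected], Y, C=config.svm_C, feature_indices=tuple(selected)
    )
    return model, selected, sel


def kfold_protocol(
    dataset: FCDataset,
    scores: PenaltyScores,
    config: PipelineConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[FoldResult], ConfusionMetrics]:
    """Stratified k-fold evaluation with selection inside each training fold.

    Returns per-fold results plus the pooled confusion over all held-out
    predictions.  Fold assignment is deterministic under a fixed seed.
    """
    config = config or PipelineConfig()
    X, Y = dataset.X, dataset.Y
    classes, counts = np.unique(Y, return_counts=True)
    if len(classes) < 2 or counts.min() < k:
        raise ValueError("stratification failure: too few subjects per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results: list[FoldResult] = []
    pooled_true, pooled_pred = [], []
    for fold, (tr, va) in enumerate(skf.split(X, Y)):
        model, selected, sel = _select_and_train(
            X[tr], Y[tr], scores, config, seed=seed + fold
        )
        m = evaluate(model, X[va][:, selected], Y[va])
        results.append(FoldResult(
            metrics=m, selected=selected, phi_star=sel.phi_star,
            lam_star=sel.lam_star, train_indices=tr.copy(),
        ))
        pooled_true.append(Y[va])
        pooled_pred.append(model.predict(X[va][:, selected]))
    pooled = confusion_from_predictions(
        np.concatenate(pooled_true), np.concatenate(pooled_pred)
    )
    return results, pooled


def leave_one_dataset_out(
    datasets: list[FCDataset],
    scores: PenaltyScores,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> dict[str, FoldResult]:
    """Hold each site out in turn; select and train on the pooled rest."""
    config = config or PipelineConfig()
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    ref = datasets[0].edge_map
    for d in datasets[1:]:
        if d.edge_map.names != ref.names:
            raise ValueError(
                f"edge map mismatch between {datasets[0].dataset_name!r} "
                f"and {d.dataset_name!r}"
            )
    out: dict[str, FoldResult] = {}
    for held in range(len(datasets)):
        rest = [d for i, d in enumerate(datasets) if i != held]
        X = np.vstack([d.X for d in rest])
        Y = np.concatenate([d.Y for d in rest])
        model, selected, sel = _select_and_train(X, Y, scores, config, seed=seed)
        test = datasets[held]
        m = evaluate(model, test.X[:, selected], test.Y)
        out[test.dataset_name] = FoldResult(
            metrics=m, selected=selected, phi_star=sel.phi_star,
            lam_star=sel.lam_star,
            train_indices=np.arange(len(Y)),
        )
    return out
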