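"""Seeded synthetic FC datasets with planted class signal.

The generator emulates edge-level group differences directly: for every
edge, both groups draw Gaussian values; on a chosen subset of *signal*
edges the group means differ by ``effect_size`` (on the pre-squash scale).
A smooth monotone squash then maps all values into (-1, 1), the range of
correlation-valued functional connectivity.  No BOLD time series are
simulated — the downstream method consumes edge features only.

The companion penalty-score generator mocks prior-knowledge feature
scores in three regimes: *informative* (signal edges strictly cheaper),
*misleading* (a disjoint decoy set cheaper), and *uniform*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import EdgeIndexMap, FCDataset
from .llm import PenaltyScores


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    effect_size is the between-group mean shift per signal edge, in
    pre-squash standard-deviation-free units; noise_sd the within-group
    standard deviation on the same scale.
    """

    n_per_class: int = 60
    N: int = 10
    signal_edges: tuple[int, ...] = (0, 7, 14, 21, 28)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    dataset_name: str = "synthetic"

    def __post_init__(self) -> None:
        p = self.N * (self.N - 1) // 2
        if self.n_per_class < 2:
            raise ValueError("need at least 2 subjects per class")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        self.signal_edges = tuple(int(j) for j in self.signal_edges)
        if any(not 0 <= j < p for j in self.signal_edges):
            raise ValueError(f"signal edge out of range for p={p}")


def _squash(z: np.ndarray) -> np.ndarray:
    """Monotone map of the real line into (-1, 1)."""
    return np.tanh(z / 2.0)


def generate_fc_dataset(spec: SyntheticSpec) -> FCDataset:
    """Draw a seeded dataset with planted group-mean differences.

    Class 1 (NC) signal-edge means sit at +effect_size/2, class 0 (SZ) at
    -effect_size/2, all other edges at 0; identical seeds give bit-identical
    datasets.  All emitted values lie strictly in (-1, 1).
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.N * (spec.N - 1) // 2
    n = 2 * spec.n_per_class
    mu = np.zeros((2, p))
    sig = np.asarray(spec.signal_edges, dtype=int)
    if sig.size:
        mu[0, sig] = -spec.effect_size / 2.0  # patients
        mu[1, sig] = +spec.effect_size / 2.0  # controls
    Y = np.concatenate([np.zeros(spec.n_per_class, int), np.ones(spec.n_per_class, int)])
    Z = rng.normal(size=(n, p)) * spec.noise_sd + mu[Y]
    X = _squash(Z)
    return FCDataset(
        X=X, Y=Y, edge_map=EdgeIndexMap.generic(spec.N),
        dataset_name=spec.dataset_name,
    )


def generate_penalty_scores(
    edge_map: EdgeIndexMap,
    signal_edges: tuple[int, ...] | list[int],
    mode: str = "informative",
    seed: int = 0,
) -> PenaltyScores:
    """Mock per-edge penalty scores (smaller = cheaper to select).

    informative: signal edges get factors in [0.1, 0.3), everything else in
    [1, 2) — so every signal edge is strictly cheaper than every non-signal
    edge.  misleading: a random decoy set of the same size, disjoint from the
    signal, gets the cheap factors instead.  uniform: all ones.
    """
    rng = np.random.default_rng(seed)
    p = len(edge_map)
    sig = np.asarray(sorted(set(int(j) for j in signal_edges)), dtype=int)
    values = rng.uniform(1.0, 2.0, size=p)
    if mode == "uniform":
        values = np.ones(p)
    elif mode == "informative":
        values[sig] = rng.uniform(0.1, 0.3, size=sig.size)
    elif mode == "misleading":
        others = np.setdiff1d(np.arange(p), sig)
        if others.size < sig.size:
            raise ValueError("not enough non-signal edges for a disjoint decoy set")
        decoy = rng.choice(others, size=sig.size, replace=False)
        values[decoy] = rng.uniform(0.1, 0.3, size=sig.size)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PenaltyScores(values=values, provenance="mock",
                         raw_response_hash=f"synthetic:{mode}:{seed}")


def write_signal_sidecar(spec: SyntheticSpec, edge_map: EdgeIndexMap, path) -> None:
    """Record the ground-truth signal edges next to a simulated dataset."""
    with open(path, "w") as fh:
        fh.write("edge_index,edge_name\n")
        for j in spec.signal_edges:
            fh.write(f"{j},{edge_map.names[j]}\n")
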