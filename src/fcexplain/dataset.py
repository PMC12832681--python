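"""Functional-connectivity edge-feature datasets.

A subject's functional brain network is an ``N x N`` symmetric connectivity
matrix over ``N`` atlas regions (ROIs).  Because the matrix is symmetric and
self-connectivity is not a feature, the strictly-upper-triangular entries are
the subject's feature vector: ``p = N(N-1)/2`` edges.  For the 90-region AAL
atlas this gives 4005 edge features per subject.

Edge ordering convention (fixed so that penalty-score vectors produced
elsewhere always align): strictly-upper-triangle, row-major, 0-based —
``(0,1), (0,2), ..., (0,N-1), (1,2), ..., (N-2,N-1)``.

Two on-disk formats are supported:

* **edge table** — delimited text, one row per subject, one column per edge
  named ``"ROIa-ROIb"``, final column ``label`` in {0, 1}
  (1 = normal control, 0 = patient);
* **matrix per subject** — a directory of delimited ``N x N`` files plus a
  ``manifest.csv`` mapping each file to its label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aal import AAL90_LABELS

SYMMETRY_TOL = 1e-8


class AsymmetricMatrixError(ValueError):
    """Connectivity matrix is not symmetric within tolerance."""


def _triu_pairs(N: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(N) for j in range(i + 1, N)]


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between edge indices and (row, col) ROI pairs, row < col."""

    N: int
    roi_labels: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...] = field(init=False)
    names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"need at least 2 regions, got N={self.N}")
        if len(self.roi_labels) != self.N:
            raise ValueError(
                f"{len(self.roi_labels)} ROI labels for N={self.N} regions"
            )
        if len(set(self.roi_labels)) != self.N:
            raise ValueError("ROI labels must be unique")
        pairs = tuple(_triu_pairs(self.N))
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(
            self,
            "names",
            tuple(
                f"{self.roi_labels[i]}-{self.roi_labels[j]}" for i, j in pairs
            ),
        )

    @classmethod
    def aal90(cls) -> "EdgeIndexMap":
        return cls(N=90, roi_labels=tuple(AAL90_LABELS))

    @classmethod
    def generic(cls, N: int) -> "EdgeIndexMap":
        """A map with placeholder labels ``ROI00..`` for synthetic work."""
        width = len(str(N - 1))
        return cls(N=N, roi_labels=tuple(f"ROI{k:0{width}d}" for k in range(N)))

    def __len__(self) -> int:
        return self.N * (self.N - 1) // 2

    def index_to_pair(self, j: int) -> tuple[int, int]:
        return edge_index_to_pair(j, self.N)

    def pair_to_index(self, i: int, j: int) -> int:
        return pair_to_edge_index(i, j, self.N)


def edge_index_to_pair(j: int, N: int) -> tuple[int, int]:
    """Map a flat edge index to its (row, col) ROI pair, row < col.

    Inverse of :func:`pair_to_edge_index` under the row-major
    upper-triangle convention.
    """
    p = N * (N - 1) // 2
    if not 0 <= j < p:
        raise IndexError(f"edge index {j} out of range for N={N} (p={p})")
    # row r starts at offset r*N - r*(r+1)/2 - r ... solve by scan; N is
    # small enough that the closed form buys nothing over a loop here, but
    # use the quadratic formula for O(1):
    # offset(r) = r*(2N - r - 1)/2, find largest r with offset(r) <= j
    r = int((2 * N - 1 - np.sqrt((2 * N - 1) ** 2 - 8 * j)) / 2)
    offset = r * (2 * N - r - 1) // 2
    while offset > j:  # guard against float edge cases
        r -= 1
        offset = r * (2 * N - r - 1) // 2
    c = r + 1 + (j - offset)
    return r, c


def pair_to_edge_index(i: int, j: int, N: int) -> int:
    """Flat edge index of ROI pair (i, j); order-insensitive, i != j."""
    if i == j:
        raise ValueError("self-connections are not edges")
    if i > j:
        i, j = j, i
    if not (0 <= i < N and 0 <= j < N):
        raise IndexError(f"pair ({i},{j}) out of range for N={N}")
    return i * (2 * N - i - 1) // 2 + (j - i - 1)


@dataclass
class ConnectivityMatrix:
    """A single subject's ``N x N`` symmetric connectivity matrix."""

    values: np.ndarray
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"expected a square matrix, got {self.values.shape}")
        N = self.values.shape[0]
        if N < 2:
            raise ValueError("need at least 2 regions")
        asym = np.abs(self.values - self.values.T)
        if asym.max() > SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise AsymmetricMatrixError(
                f"matrix asymmetric at ({i},{j}): "
                f"A[{i},{j}]={self.values[i, j]!r} vs A[{j},{i}]={self.values[j, i]!r}"
            )
        if self.roi_labels is None:
            self.roi_labels = tuple(EdgeIndexMap.generic(N).roi_labels)
        elif len(self.roi_labels) != N:
            raise ValueError("roi_labels length does not match matrix size")

    @property
    def N(self) -> int:
        return self.values.shape[0]


def vectorize_upper_triangle(A: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Extract the strictly-upper-triangular entries as an edge vector.

    The diagonal (self-connectivity) is ignored.  Length is ``N(N-1)/2``;
    ordering is row-major over pairs with ``i < j``.
    """
    if not isinstance(A, ConnectivityMatrix):
        A = ConnectivityMatrix(A)
    iu = np.triu_indices(A.N, k=1)
    return A.values[iu].copy()


def devectorize(edges: np.ndarray, N: int, diagonal: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric ``N x N`` matrix from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    p = N * (N - 1) // 2
    if edges.shape != (p,):
        raise ValueError(f"expected {p} edges for N={N}, got {edges.shape}")
    A = np.full((N, N), diagonal, dtype=float)
    iu = np.triu_indices(N, k=1)
    A[iu] = edges
    A[(iu[1], iu[0])] = edges
    return A


@dataclass
class FCDataset:
    """An ``n x p`` subjects-by-edges feature matrix with binary labels.

    Label convention: 1 = normal control (NC), 0 = patient (SZ).
    """

    X: np.ndarray
    Y: np.ndarray
    edge_map: EdgeIndexMap
    dataset_name: str = "unnamed"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x edges)")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"{self.X.shape[0]} subjects in X but {self.Y.shape[0]} labels"
            )
        if self.X.shape[1] != len(self.edge_map):
            raise ValueError(
                f"X has {self.X.shape[1]} edges but edge map has {len(self.edge_map)}"
            )
        if not np.isin(self.Y, (0, 1)).all():
            bad = self.Y[~np.isin(self.Y, (0, 1))][0]
            raise ValueError(f"labels must be 0 or 1, found {bad!r}")
        self.Y = self.Y.astype(int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.edge_map.names))
        df["label"] = self.Y
        return df


def from_matrices(
    matrices: list[ConnectivityMatrix | np.ndarray],
    labels: list[int],
    roi_labels: tuple[str, ...] | None = None,
    dataset_name: str = "unnamed",
) -> FCDataset:
    """Vectorize a list of per-subject connectivity matrices into a dataset."""
    if len(matrices) != len(labels):
        raise ValueError("one label per matrix required")
    rows = [vectorize_upper_triangle(A) for A in matrices]
    first = matrices[0]
    N = first.N if isinstance(first, ConnectivityMatrix) else np.asarray(first).shape[0]
    if roi_labels is None and isinstance(first, ConnectivityMatrix):
        roi_labels = tuple(first.roi_labels)
    edge_map = (
        EdgeIndexMap(N=N, roi_labels=tuple(roi_labels))
        if roi_labels is not None
        else EdgeIndexMap.generic(N)
    )
    return FCDataset(
        X=np.vstack(rows), Y=np.asarray(labels), edge_map=edge_map,
        dataset_name=dataset_name,
    )


# ---------------------------------------------------------------------------
# I/O


def write_dataset(dataset: FCDataset, path: str | os.PathLike, sep: str = ",") -> None:
    """Write the edge-table form: one row per subject, final column ``label``."""
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def _edge_map_from_names(names: list[str]) -> EdgeIndexMap:
    p = len(names)
    # invert p = N(N-1)/2
    N = int(round((1 + np.sqrt(1 + 8 * p)) / 2))
    if N * (N - 1) // 2 != p:
        raise ValueError(f"{p} edge columns do not form a full upper triangle")
    roi_labels: list[str] = []
    seen: set[str] = set()
    for name in names:
        for part in name.split("-"):
            if part not in seen:
                seen.add(part)
                roi_labels.append(part)
    if len(roi_labels) != N:
        # fall back to generic labels when names are not parseable ROI pairs
        return EdgeIndexMap.generic(N)
    em = EdgeIndexMap(N=N, roi_labels=tuple(roi_labels))
    if tuple(names) != em.names:
        return EdgeIndexMap.generic(N)
    return em


def read_dataset(
    path: str | os.PathLike,
    format: str = "edge-table",
    sep: str = ",",
    dataset_name: str | None = None,
) -> FCDataset:
    """Read a dataset from disk.

    ``format="edge-table"`` reads a single delimited file; ``"matrix-per-subject"``
    reads a directory of square matrix files listed in its ``manifest.csv``
    (columns ``file,label``).
    """
    if format == "edge-table":
        return _read_edge_table(path, sep=sep, dataset_name=dataset_name)
    if format == "matrix-per-subject":
        return _read_matrix_dir(path, sep=sep, dataset_name=dataset_name)
    raise ValueError(f"unknown format {format!r}")


def _read_edge_table(path, sep=",", dataset_name=None) -> FCDataset:
    try:
        df = pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, ValueError) as e:
        raise ValueError(f"malformed edge table {path}: {e}") from e
    if "label" not in df.columns:
        raise ValueError(f"edge table {path} lacks the required 'label' column")
    labels = df["label"].to_numpy()
    feats = df.drop(columns=["label"])
    bad = feats.columns[[not pd.api.types.is_numeric_dtype(feats[c]) for c in feats.columns]]
    if len(bad):
        raise ValueError(f"non-numeric feature column(s): {list(bad)[:3]}")
    edge_map = _edge_map_from_names(list(feats.columns))
    name = dataset_name or os.path.splitext(os.path.basename(str(path)))[0]
    return FCDataset(X=feats.to_numpy(dtype=float), Y=labels, edge_map=edge_map,
                     dataset_name=name)


def _read_matrix_dir(path, sep=",", dataset_name=None) -> FCDataset:
    manifest_path = os.path.join(str(path), "manifest.csv")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"missing manifest.csv in {path}")
    manifest = pd.read_csv(manifest_path)
    for col in ("file", "label"):
        if col not in manifest.columns:
            raise ValueError(f"manifest must have a '{col}' column")
    matrices, labels = [], []
    for _, row in manifest.iterrows():
        fp = os.path.join(str(path), str(row["file"]))
        try:
            vals = np.loadtxt(fp, delimiter=sep)
        except ValueError as e:
            raise ValueError(f"malformed matrix file {fp}: {e}") from e
        matrices.append(ConnectivityMatrix(vals))
        labels.append(int(row["label"]))
    name = dataset_name or os.path.basename(os.path.normpath(str(path)))
    return from_matrices(matrices, labels, dataset_name=name)
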