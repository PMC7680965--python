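"""SMOTE oversampling to balance Hoehn & Yahr stage classes.

The stage-3 class is heavily under-represented (10 of 93 patients in the
reference cohort), which biases any classifier toward the majority stages.
Synthetic minority oversampling (SMOTE; Chawla et al. 2002) creates new
minority points by linear interpolation between a real sample and one of
its k nearest same-class neighbours, populating the minority manifold
rather than duplicating points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

DEFAULT_K_NEIGHBORS = 5

#: oversampling amounts reproducing the reference cohort's balanced design:
#: +20 synthetic stage-3 and +28 synthetic stage-2.5 samples
DEFAULT_SMOTE_AMOUNTS: dict[float, int] = {3.0: 20, 2.5: 28, 2.0: 0}


@dataclass
class LabeledFeatureMatrix:
    """Design matrix with class labels and per-row real/synthetic provenance."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.provenance is None:
            self.provenance = np.array(["REAL"] * len(self.y))
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be n x p with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing/non-finite values")
        if len(self.y) == 0:
            raise ValueError("class set must be non-empty")

    @property
    def n(self) -> int:
        return self.X.shape[0]


def class_distribution(y) -> dict[Hashable, tuple[int, float]]:
    """Per-class (count, percent of total) with percents at 2 decimals."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("y is empty")
    out: dict[Hashable, tuple[int, float]] = {}
    labels, counts = np.unique(y, return_counts=True)
    total = len(y)
    for lab, cnt in zip(labels, counts):
        out[lab.item() if hasattr(lab, "item") else lab] = (
            int(cnt),
            round(cnt / total * 100.0, 2),
        )
    return out


def smote(
    data: LabeledFeatureMatrix,
    amounts: Mapping[Hashable, int] | None = None,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> LabeledFeatureMatrix:
    """Append SMOTE-interpolated synthetic rows for the requested classes.

    For every synthetic sample of class ``c`` a real member ``x`` is taken
    (cycling through a seeded random permutation of the class), one of its
    ``k`` nearest real same-class neighbours ``x_n`` is drawn, and the new
    point is ``x + u (x_n - x)`` with ``u ~ U[0, 1]``.  Neighbourhoods are
    computed on a min-max-scaled copy of X so no feature dominates the
    Euclidean distance; interpolation itself happens in original units, so
    every synthetic value lies between its two parents feature-wise.  Real
    rows are passed through unchanged and order-preserved.
    """
    if amounts is None:
        amounts = DEFAULT_SMOTE_AMOUNTS
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if any(a < 0 for a in amounts.values()):
        raise ValueError("amounts must be non-negative")
    rng = np.random.default_rng(seed)

    # min-max scale a copy for distance computation only
    lo, hi = data.X.min(axis=0), data.X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (data.X - lo) / span

    new_rows: list[np.ndarray] = []
    new_y: list = []
    for cls in sorted(amounts, key=str):
        amount = int(amounts[cls])
        if amount == 0:
            continue
        idx = np.flatnonzero(data.y == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} absent from y")
        if idx.size < 2:
            raise ValueError(
                f"class {cls!r} has a single member; SMOTE needs >= 2"
            )
        k = k_neighbors
        if k >= idx.size:
            k = idx.size - 1
            warnings.warn(
                f"k_neighbors clamped to {k} for class {cls!r} of size {idx.size}",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xs[idx])
        _, nbrs = nn.kneighbors(Xs[idx])  # column 0 is the point itself
        order = rng.permutation(idx.size)
        for t in range(amount):
            i = order[t % idx.size]
            x = data.X[idx[i]]
            x_n = data.X[idx[nbrs[i, rng.integers(1, k + 1)]]]
            u = rng.uniform()
            new_rows.append(x + u * (x_n - x))
            new_y.append(cls)

    if not new_rows:
        return replace(
            data,
            X=data.X.copy(),
            y=data.y.copy(),
            provenance=data.provenance.copy(),
        )
    X_out = np.vstack([data.X, np.array(new_rows)])
    y_out = np.concatenate([data.y, np.array(new_y, dtype=data.y.dtype)])
    prov = np.concatenate([data.provenance, np.array(["SYNTHETIC"] * len(new_rows))])
    return LabeledFeatureMatrix(X_out, y_out, list(data.feature_names), prov)
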