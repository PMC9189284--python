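"""SMOTE class balancing by k-nearest-neighbour interpolation.

Each synthetic minority-class sample is drawn on the segment between a random
class member x and one of its k nearest same-class neighbours x_nn:

    x_new = x + zeta * (x_nn - x),   zeta ~ Uniform[0, 1]

repeated until every class reaches the majority-class count.  Distances are
Euclidean on the feature columns currently in play; k is truncated to
(class size - 1) when a class is smaller than k + 1.  Synthetic values are
convex combinations, so non-negativity and per-coordinate bounds of the
seed/neighbour pair are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import LabelledMatrix
from .errors import ConfigurationError, ValidationError

__all__ = ["BalancedMatrix", "smote_balance", "smote_arrays"]


@dataclass
class BalancedMatrix:
    """A balanced LabelledMatrix: originals first (unchanged, original order),
    synthetic cells appended with ``is_synthetic`` flags and, for auditing,
    the (seed_row, neighbour_row) provenance of every synthetic cell."""

    data: LabelledMatrix
    is_synthetic: np.ndarray
    provenance: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_synthetic(self) -> int:
        return int(self.is_synthetic.sum())


def smote_arrays(
    X: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Array-level SMOTE used both by :func:`smote_balance` and inside CV folds.

    Returns (synthetic rows, their labels, provenance as (seed_row,
    neighbour_row) indices into ``X``).  Deterministic given ``rng`` state.
    """
    if k < 1:
        raise ConfigurationError("SMOTE k must be >= 1")
    y = np.asarray(y, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    singletons = [str(c) for c, n in zip(classes, counts) if n < 2]
    if singletons:
        raise ValidationError(f"SMOTE needs >=2 cells per class; classes with one cell: {singletons}")
    target = int(counts.max())

    new_rows: list[np.ndarray] = []
    new_labels: list[object] = []
    provenance: list[tuple[int, int]] = []
    for cls, count in zip(classes, counts):
        need = target - int(count)
        if need == 0:
            continue
        idx = np.flatnonzero(y == cls)
        Xc = X[idx]
        k_eff = min(k, len(idx) - 1)
        dist = cdist(Xc, Xc)
        np.fill_diagonal(dist, np.inf)
        # k_eff nearest same-class neighbours of every class member
        nn = np.argsort(dist, axis=1, kind="stable")[:, :k_eff]
        for _ in range(need):
            i = int(rng.integers(len(idx)))
            j = int(nn[i, rng.integers(k_eff)])
            zeta = rng.random()
            new_rows.append(Xc[i] + zeta * (Xc[j] - Xc[i]))
            new_labels.append(cls)
            provenance.append((int(idx[i]), int(idx[j])))
    if not new_rows:
        return np.empty((0, X.shape[1])), np.empty(0, dtype=object), []
    return np.vstack(new_rows), np.asarray(new_labels, dtype=object), provenance


def smote_balance(data: LabelledMatrix, k: int = 5, seed: int = 0) -> BalancedMatrix:
    """Balance every class up to the majority count.

    Original cells appear unchanged and first, in their original order;
    synthetic cells are appended with generated ids.  Already-balanced input
    is returned as-is (zero synthetic cells).
    """
    rng = np.random.default_rng(seed)
    X = data.values
    y = data.label_array()
    synth, synth_labels, provenance = smote_arrays(X, y, k, rng)

    values = np.vstack([X, synth]) if len(synth) else X.copy()
    cell_ids = list(data.cell_ids) + [f"smote{j + 1:05d}" for j in range(len(synth))]
    labels = list(data.labels) + [str(l) for l in synth_labels]
    flags = np.zeros(len(cell_ids), dtype=bool)
    flags[data.n_cells:] = True
    balanced = LabelledMatrix(values, cell_ids, list(data.gene_ids), labels)
    return BalancedMatrix(data=balanced, is_synthetic=flags, provenance=provenance)
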