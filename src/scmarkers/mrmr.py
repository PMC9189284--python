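"""Greedy max-relevance min-redundancy (mRMR) feature ranking.

Expression vectors are discretized into three states (below / within / above
mean +- sigma*sd) and mutual information is estimated by the plug-in formula

    MI(u, v) = sum_{a,b} p(a, b) ln[ p(a, b) / (p(a) p(b)) ]        (nats)

on the joint empirical histogram.  Relevance of a feature is MI(feature,
class label); redundancy against the already-selected set S is the mean
MI(feature, s) over s in S.  The greedy ranking repeatedly selects the
unselected feature maximizing

    phi = relevance - redundancy

(the MID variant), starting from the single most relevant feature, until all
features are ranked.  Ties break toward the lower input column index so the
ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import LabelledMatrix
from .errors import ValidationError

__all__ = ["RankedList", "discretize", "mutual_information", "rank_mrmr"]


@dataclass
class RankedList:
    """Ordered (gene_id, phi_score) pairs; the first entry's score is its
    relevance alone, later scores are phi at the step the feature was picked."""

    entries: list[tuple[str, float]]

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def head(self, n: int) -> "RankedList":
        return RankedList(self.entries[:n])


def discretize(x, sigma: float = 1.0) -> np.ndarray:
    """Map a real vector to 3 states by thresholds mean +- sigma*sd.

    0 = below (x < mean - sigma*sd), 1 = within, 2 = above
    (x > mean + sigma*sd).  A constant vector maps to the single "within"
    state.  Invariant to affine rescaling x -> a*x + b with a > 0, since the
    thresholds co-scale.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("discretize requires finite input")
    sd = x.std()
    if sd == 0:
        return np.ones(x.shape, dtype=np.int8)
    mean = x.mean()
    states = np.ones(x.shape, dtype=np.int8)
    states[x < mean - sigma * sd] = 0
    states[x > mean + sigma * sd] = 2
    return states


def _encode(v) -> tuple[np.ndarray, int]:
    """Integer-code an arbitrary state vector as 0..K-1."""
    _, inv = np.unique(np.asarray(v), return_inverse=True)
    return inv.astype(np.int64), int(inv.max()) + 1


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def mutual_information(u, v) -> float:
    """Plug-in mutual information (nats) between two discrete state vectors."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.size == 0:
        raise ValidationError("mutual_information requires equal non-zero length vectors")
    ui, ku = _encode(u)
    vi, kv = _encode(v)
    joint = np.bincount(ui * kv + vi, minlength=ku * kv).reshape(ku, kv).astype(float)
    return _mi_from_joint(joint)


def _mi_against_columns(states: np.ndarray, cols: np.ndarray, v: np.ndarray, kv: int) -> np.ndarray:
    """MI of integer vector ``v`` (states 0..kv-1) against each listed column
    of the 3-state matrix ``states``.  Vectorised joint histograms."""
    out = np.empty(len(cols))
    for i, c in enumerate(cols):
        joint = np.bincount(states[:, c] * kv + v, minlength=3 * kv).reshape(3, kv).astype(float)
        out[i] = _mi_from_joint(joint)
    return out


def rank_mrmr(data: LabelledMatrix, sigma: float = 1.0, top: int | None = None) -> RankedList:
    """Rank every feature of ``data`` by the greedy mRMR criterion.

    Parameters
    ----------
    data
        Labelled expression matrix; features are discretized column-wise.
    sigma
        Width multiplier of the 3-state discretization thresholds.
    top
        If given, stop after ranking the first ``top`` selections (a prefix
        of the full ranking — the greedy order does not depend on how far it
        is run).  Default ranks all features.

    Pairwise redundancy terms are accumulated incrementally (each MI(f, s)
    is computed exactly once, when s is selected); the result is identical
    to re-computing every MI from scratch at every step.
    """
    g = data.n_genes
    if g < 1:
        raise ValidationError("rank_mrmr requires at least one feature")
    n_rank = g if top is None else max(1, min(top, g))

    states = np.empty((data.n_cells, g), dtype=np.int64)
    for j in range(g):
        states[:, j] = discretize(data.values[:, j], sigma=sigma)
    labels, k_lab = _encode(data.label_array())

    remaining = np.arange(g)
    relevance = _mi_against_columns(states, remaining, labels, k_lab)
    red_sum = np.zeros(g)  # cumulative sum of MI(f, s) over selected s

    entries: list[tuple[str, float]] = []
    # first pick: pure relevance (criterion with empty S); ties -> lower index
    best = int(remaining[np.argmax(relevance)])
    entries.append((data.gene_ids[best], float(relevance[best])))
    selected_last = best
    mask = remaining != best
    remaining = remaining[mask]
    relevance = relevance[mask]

    while len(entries) < n_rank:
        red_sum[remaining] += _mi_against_columns(states, remaining, states[:, selected_last], 3)
        phi = relevance - red_sum[remaining] / len(entries)
        i = int(np.argmax(phi))  # argmax returns the first (lowest-index) maximiser
        best = int(remaining[i])
        entries.append((data.gene_ids[best], float(phi[i])))
        selected_last = best
        keep = np.arange(len(remaining)) != i
        remaining = remaining[keep]
        relevance = relevance[keep]

    return RankedList(entries)
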