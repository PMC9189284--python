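"""All-relevant feature filtering with shadow variables (Boruta).

Every iteration appends one shadow column per live feature — a row
permutation of the original column, so the shadow carries the feature's
marginal distribution but no class association — fits a 100-tree random
forest on [live + shadow] columns, and records mean-impurity-decrease
importances.  A live feature scores a *hit* when its importance strictly
exceeds the maximum shadow importance of that iteration (ties count as no
hit).  After each iteration every still-undecided feature's hit count is
tested two-sidedly against Binomial(iterations, 0.5) with Bonferroni
correction across the undecided features: significantly more hits confirms
the feature, significantly fewer rejects it and removes it (with its
shadow) from subsequent iterations.  The loop stops when no feature is
undecided or ``max_iter`` is reached; leftovers are *tentative*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from .data_io import LabelledMatrix
from .errors import ConfigurationError, ConsistencyError, ValidationError

__all__ = ["BorutaResult", "run_boruta", "filter_matrix"]

CONFIRMED, REJECTED, TENTATIVE = "confirmed", "rejected", "tentative"


@dataclass
class BorutaResult:
    """Per-feature verdicts plus the full importance history.

    ``confirmed`` is ordered by (confirmation iteration, input column index);
    ``importance_history`` has one row per completed iteration, with a column
    per feature and a ``<feature>::shadow`` column for its shadow (NaN once a
    feature has been removed).  ``confirmed``, ``rejected`` and ``tentative``
    partition the input features.
    """

    confirmed: list[str]
    rejected: set[str] = field(repr=False)
    tentative: set[str] = field(repr=False)
    importance_history: pd.DataFrame = field(repr=False)
    n_iterations_run: int = 0


def _make_shadows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One shadow per column: an independent row permutation of that column."""
    return np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])


def run_boruta(
    data: LabelledMatrix,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_trees: int = 100,
) -> BorutaResult:
    """Run the shadow-variable filter; deterministic given ``seed``."""
    if max_iter < 1:
        raise ConfigurationError("max_iter must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    data.require_trainable()

    rng = np.random.default_rng(seed)
    y = data.label_array().astype(str)
    gene_ids = list(data.gene_ids)
    n_feat = len(gene_ids)

    live = np.arange(n_feat)          # undecided + confirmed stay in the model
    status = np.full(n_feat, TENTATIVE, dtype=object)
    hits = np.zeros(n_feat, dtype=int)
    confirmed_at: dict[int, int] = {}
    history_rows: list[dict[str, float]] = []

    it = 0
    while it < max_iter and np.any(status == TENTATIVE):
        it += 1
        X_live = data.values[:, live]
        shadows = _make_shadows(X_live, rng)
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31))
        )
        forest.fit(np.hstack([X_live, shadows]), y)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[: len(live)], imp[len(live):]
        threshold = shadow_imp.max()
        hits[live[real_imp > threshold]] += 1  # strict: ties are no hit

        row: dict[str, float] = {}
        for pos, j in enumerate(live):
            row[gene_ids[j]] = float(real_imp[pos])
            row[f"{gene_ids[j]}::shadow"] = float(shadow_imp[pos])
        history_rows.append(row)

        undecided = np.flatnonzero(status == TENTATIVE)
        m = len(undecided)
        for j in undecided:
            p = binomtest(int(hits[j]), n=it, p=0.5, alternative="two-sided").pvalue
            if p * m < alpha:  # Bonferroni across currently undecided features
                if hits[j] > it / 2:
                    status[j] = CONFIRMED
                    confirmed_at[j] = it
                else:
                    status[j] = REJECTED
        live = np.flatnonzero(status != REJECTED)

    confirmed = sorted(confirmed_at, key=lambda j: (confirmed_at[j], j))
    history = pd.DataFrame(history_rows)
    history.index = pd.RangeIndex(1, it + 1, name="iteration")
    return BorutaResult(
        confirmed=[gene_ids[j] for j in confirmed],
        rejected={gene_ids[j] for j in np.flatnonzero(status == REJECTED)},
        tentative={gene_ids[j] for j in np.flatnonzero(status == TENTATIVE)},
        importance_history=history,
        n_iterations_run=it,
    )


def filter_matrix(
    data: LabelledMatrix, result: BorutaResult, keep_tentative: bool = False
) -> LabelledMatrix:
    """Restrict ``data`` to confirmed (plus tentative, if flagged) features,
    preserving cell order and labels."""
    known = set(data.gene_ids)
    referenced = set(result.confirmed) | result.rejected | result.tentative
    unknown = referenced - known
    if unknown:
        raise ConsistencyError(f"Boruta result refers to unknown gene ids: {sorted(unknown)[:10]}")
    keep = set(result.confirmed) | (result.tentative if keep_tentative else set())
    selected = [g for g in data.gene_ids if g in keep]
    if not selected:
        raise ValidationError("no features survive Boruta filtering")
    return data.subset_genes(selected)
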