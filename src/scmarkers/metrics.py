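"""Multi-class evaluation statistics: Gorodkin's K-category MCC, overall
accuracy, and per-class accuracy.

The multi-class Matthews correlation coefficient treats truth and prediction
as one-hot N x K indicator matrices Y and X and returns

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y))

with cov(A, B) = sum_{n,k} (A_nk - mean_k(A)) (B_nk - mean_k(B)).  Its range
is [-1, 1]: 1 for perfect agreement, 0 for no-better-than-random, -1 for
total disagreement.  When either denominator covariance vanishes (constant
truth or constant prediction) the coefficient is undefined and the
"no better than random" value 0 is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["Evaluation", "multiclass_mcc", "evaluate", "confusion_table"]


@dataclass
class Evaluation:
    """MCC, overall accuracy, per-class accuracy and the confusion table.

    ``per_class_acc`` is defined only for classes present in the truth;
    ``confusion`` rows are true classes, columns predicted classes, over the
    lexicographically ordered union alphabet.
    """

    mcc: float
    acc: float
    per_class_acc: dict[str, float]
    confusion: pd.DataFrame


def _alphabet(y_true: Sequence[Hashable], y_pred: Sequence[Hashable]) -> list:
    return sorted({*y_true, *y_pred}, key=str)


def _check(y_true, y_pred) -> tuple[list, list]:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) == 0:
        raise ValidationError("empty label sequences")
    if len(y_true) != len(y_pred):
        raise ValidationError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    return y_true, y_pred


def multiclass_mcc(y_true: Sequence[Hashable], y_pred: Sequence[Hashable]) -> float:
    """K-category MCC via one-hot covariances; 0 on a vanishing denominator."""
    y_true, y_pred = _check(y_true, y_pred)
    alpha = {c: k for k, c in enumerate(_alphabet(y_true, y_pred))}
    n, k = len(y_true), len(alpha)
    Y = np.zeros((n, k))
    X = np.zeros((n, k))
    Y[np.arange(n), [alpha[c] for c in y_true]] = 1.0
    X[np.arange(n), [alpha[c] for c in y_pred]] = 1.0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float((Xc * Yc).sum())
    cov_xx = float((Xc * Xc).sum())
    cov_yy = float((Yc * Yc).sum())
    if cov_xx == 0.0 or cov_yy == 0.0:
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def confusion_table(y_true: Sequence[Hashable], y_pred: Sequence[Hashable]) -> pd.DataFrame:
    """K x K integer confusion table (rows true, columns predicted) over the
    lexicographically ordered union label alphabet."""
    y_true, y_pred = _check(y_true, y_pred)
    alpha = _alphabet(y_true, y_pred)
    idx = {c: k for k, c in enumerate(alpha)}
    table = np.zeros((len(alpha), len(alpha)), dtype=int)
    for t, p in zip(y_true, y_pred):
        table[idx[t], idx[p]] += 1
    return pd.DataFrame(table, index=alpha, columns=alpha)


def evaluate(y_true: Sequence[Hashable], y_pred: Sequence[Hashable]) -> Evaluation:
    """Full evaluation: MCC, overall ACC (confusion trace over total), and
    per-class ACC (diagonal entry over row sum, truth-present classes only)."""
    y_true, y_pred = _check(y_true, y_pred)
    confusion = confusion_table(y_true, y_pred)
    diag = np.diag(confusion.to_numpy())
    row_sums = confusion.to_numpy().sum(axis=1)
    acc = float(diag.sum() / confusion.to_numpy().sum())
    per_class = {
        str(c): float(diag[i] / row_sums[i])
        for i, c in enumerate(confusion.index)
        if row_sums[i] > 0
    }
    return Evaluation(
        mcc=multiclass_mcc(y_true, y_pred), acc=acc, per_class_acc=per_class, confusion=confusion
    )
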