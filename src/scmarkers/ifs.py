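"""Incremental feature selection (IFS).

From an mRMR-ranked feature list, nested prefixes (step, 2*step, ..., all
features) are evaluated by stratified k-fold cross-validation with one of
three fixed classifier families — random forest (100 trees, Gini), 1-nearest
neighbour (Minkowski exponent 2), and a fully grown CART/Gini decision tree.
Held-out predictions are pooled over folds into a single confusion table and
scored with the multi-class MCC; the record with maximum MCC is the *optimal*
classifier, and the smallest prefix within ``delta`` of that maximum is the
*compact* one.  One shared fold assignment is used across every subset size
of a curve so that curve differences reflect features, not fold noise.

SMOTE balancing is applied inside each training fold by default
(``smote_mode="fold_internal"``); ``"global"`` instead synthesizes minority
samples once from the full data and adds them to every training fold.  Test
folds never contain synthetic cells, so reported scores are always on
original cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .data_io import LabelledMatrix
from .errors import ConfigurationError, ConsistencyError, ValidationError
from .metrics import Evaluation, evaluate
from .mrmr import RankedList
from .smote import smote_arrays

__all__ = [
    "ClassifierSpec",
    "IFSRecord",
    "IFSCurve",
    "build_subsets",
    "cross_validate",
    "run_ifs",
    "select_optimal",
    "select_compact",
    "fit_final",
    "FittedClassifier",
]

ALGORITHMS = ("random_forest", "knn", "decision_tree")
SMOTE_MODES = ("fold_internal", "global", "off")

_DEFAULTS: dict[str, dict] = {
    "random_forest": {"n_trees": 100},
    "knn": {"n_neighbors": 1, "minkowski_p": 2},
    "decision_tree": {"max_depth": None},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the three fixed classifier families with its documented knobs."""

    algorithm: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        bad = set(self.parameters) - set(_DEFAULTS[self.algorithm])
        if bad:
            raise ConfigurationError(
                f"unsupported parameters for {self.algorithm}: {sorted(bad)} "
                f"(allowed: {sorted(_DEFAULTS[self.algorithm])})"
            )

    def resolved(self) -> dict:
        return {**_DEFAULTS[self.algorithm], **self.parameters}


def make_classifier(spec: ClassifierSpec, seed: int):
    p = spec.resolved()
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=p["n_trees"], criterion="gini", random_state=seed)
    if spec.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=p["n_neighbors"], metric="minkowski", p=p["minkowski_p"])
    return DecisionTreeClassifier(criterion="gini", max_depth=p["max_depth"], random_state=seed)


@dataclass
class IFSRecord:
    n_features: int
    evaluation: Evaluation


@dataclass
class IFSCurve:
    algorithm: ClassifierSpec
    records: list[IFSRecord]
    step: int
    cv_folds: int
    seed: int


def build_subsets(ranked: RankedList, step: int = 1) -> list[list[str]]:
    """Nested prefixes of lengths step, 2*step, ..., always ending with the
    full ranked list."""
    if step < 1:
        raise ConfigurationError("IFS step must be >= 1")
    ids = ranked.gene_ids
    sizes = list(range(step, len(ids) + 1, step))
    if not sizes or sizes[-1] != len(ids):
        sizes.append(len(ids))
    return [ids[:s] for s in sizes]


def stratified_fold_assignment(labels, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Per-cell fold ids; each class is spread round-robin over folds so any
    class imbalance between folds is at most one cell.  Classes smaller than
    the fold count simply miss some folds."""
    labels = np.asarray(labels, dtype=object)
    assign = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        offset = int(rng.integers(folds))
        assign[idx] = (offset + np.arange(len(idx))) % folds
    return assign


def _global_synth(X, y, k, seed):
    synth, synth_labels, _ = smote_arrays(X, y, k, np.random.default_rng(seed))
    return synth, synth_labels


def cross_validate(
    data: LabelledMatrix,
    features,
    spec: ClassifierSpec,
    folds: int = 10,
    smote_mode: str = "fold_internal",
    seed: int = 0,
    smote_k: int = 5,
    fold_assignment: np.ndarray | None = None,
) -> Evaluation:
    """Stratified k-fold CV on a feature prefix; pooled held-out evaluation.

    Every cell is predicted exactly once; the pooled truth/prediction pair is
    scored by :func:`scmarkers.metrics.evaluate`.
    """
    if folds < 2:
        raise ConfigurationError("cross-validation needs folds >= 2")
    if smote_mode not in SMOTE_MODES:
        raise ConfigurationError(f"unknown smote_mode {smote_mode!r}; choose from {SMOTE_MODES}")
    data.require_trainable()
    cols = data.gene_index(list(features))
    if len(cols) == 0:
        raise ValidationError("empty feature prefix")
    X = data.values[:, cols]
    y = data.label_array()

    rng = np.random.default_rng(seed)
    if fold_assignment is None:
        fold_assignment = stratified_fold_assignment(y, folds, rng)
    clf_seed = int(np.random.default_rng(seed + 1).integers(2**31))
    smote_seed = int(np.random.default_rng(seed + 2).integers(2**31))

    if smote_mode == "global":
        g_synth, g_synth_labels = _global_synth(X, y, smote_k, smote_seed)

    y_pred = np.empty(len(y), dtype=object)
    for f in range(folds):
        test = fold_assignment == f
        if not test.any():
            continue
        X_tr, y_tr = X[~test], y[~test]
        if smote_mode == "fold_internal":
            synth, synth_labels, _ = smote_arrays(
                X_tr, y_tr, smote_k, np.random.default_rng(smote_seed + f)
            )
            if len(synth):
                X_tr = np.vstack([X_tr, synth])
                y_tr = np.concatenate([y_tr, synth_labels])
        elif smote_mode == "global" and len(g_synth):
            X_tr = np.vstack([X_tr, g_synth])
            y_tr = np.concatenate([y_tr, g_synth_labels])
        absent = set(y[test]) - set(y_tr)
        if absent:
            warnings.warn(f"fold {f}: classes absent from training: {sorted(map(str, absent))}")
        clf = make_classifier(spec, clf_seed)
        clf.fit(X_tr, y_tr.astype(str))
        y_pred[test] = clf.predict(X[test])
    return evaluate([str(t) for t in y], [str(p) for p in y_pred])


def run_ifs(
    data: LabelledMatrix,
    ranked: RankedList,
    spec: ClassifierSpec,
    step: int = 1,
    folds: int = 10,
    smote_mode: str = "fold_internal",
    seed: int = 0,
    smote_k: int = 5,
) -> IFSCurve:
    """Evaluate every nested prefix of ``ranked`` with one shared stratified
    fold assignment; returns the full IFS curve."""
    subsets = build_subsets(ranked, step)
    assignment = stratified_fold_assignment(
        data.label_array(), folds, np.random.default_rng(seed)
    )
    records = [
        IFSRecord(
            n_features=len(fs),
            evaluation=cross_validate(
                data, fs, spec, folds=folds, smote_mode=smote_mode, seed=seed,
                smote_k=smote_k, fold_assignment=assignment,
            ),
        )
        for fs in subsets
    ]
    return IFSCurve(algorithm=spec, records=records, step=step, cv_folds=folds, seed=seed)


def select_optimal(curve: IFSCurve) -> IFSRecord:
    """The record with maximum MCC; ties break toward fewer features."""
    if not curve.records:
        raise ValidationError("empty IFS curve")
    return max(curve.records, key=lambda r: (r.evaluation.mcc, -r.n_features))


def select_compact(curve: IFSCurve, delta: float = 0.01) -> IFSRecord:
    """The smallest prefix whose MCC is within ``delta`` of the curve maximum."""
    if delta < 0:
        raise ConfigurationError("delta must be >= 0")
    best = select_optimal(curve).evaluation.mcc
    for rec in sorted(curve.records, key=lambda r: r.n_features):
        if rec.evaluation.mcc >= best - delta:
            return rec
    raise AssertionError("unreachable: the optimal record always qualifies")


@dataclass
class FittedClassifier:
    """A trained classifier together with its feature list and spec, so it can
    be persisted and re-applied to new matrices."""

    estimator: object
    feature_ids: list[str]
    spec: ClassifierSpec

    def predict(self, data: LabelledMatrix) -> list[str]:
        try:
            cols = data.gene_index(self.feature_ids)
        except ValidationError as exc:
            raise ConsistencyError(f"matrix lacks required genes: {exc}") from exc
        return [str(p) for p in self.estimator.predict(data.values[:, cols])]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FittedClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, FittedClassifier):
            raise ConsistencyError(f"{path} does not contain a FittedClassifier")
        return obj


def fit_final(
    data: LabelledMatrix,
    features,
    spec: ClassifierSpec,
    smote_mode: str = "fold_internal",
    seed: int = 0,
    smote_k: int = 5,
) -> FittedClassifier:
    """Fit one classifier on all cells (optionally SMOTE-balanced) for reuse."""
    features = list(features)
    if not features:
        raise ValidationError("fit_final requires a non-empty feature list")
    if smote_mode not in SMOTE_MODES:
        raise ConfigurationError(f"unknown smote_mode {smote_mode!r}")
    cols = data.gene_index(features)
    X, y = data.values[:, cols], data.label_array()
    if smote_mode != "off":
        synth, synth_labels, _ = smote_arrays(X, y, smote_k, np.random.default_rng(seed + 2))
        if len(synth):
            X = np.vstack([X, synth])
            y = np.concatenate([y, synth_labels])
    clf = make_classifier(spec, int(np.random.default_rng(seed + 1).integers(2**31)))
    clf.fit(X, y.astype(str))
    return FittedClassifier(estimator=clf, feature_ids=features, spec=spec)
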