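import numpy as np
import pytest

from scmarkers import (
    ClassifierSpec,
    ConfigurationError,
    SyntheticConfig,
    build_subsets,
    cross_validate,
    evaluate,
    fit_final,
    generate,
    run_ifs,
    select_compact,
    select_optimal,
)
from scmarkers.errors import ConsistencyError
from scmarkers.ifs import FittedClassifier, IFSCurve, IFSRecord
from scmarkers.mrmr import RankedList


def _ranked(ids):
    return RankedList([(g, 0.0) for g in ids])


def _curve(pairs):
    """Build an IFSCurve from (n_features, mcc) pairs via dummy evaluations."""
    records = []
    for n, mcc in pairs:
        ev = evaluate(["a", "b"], ["a", "b"])
        ev.mcc = mcc
        records.append(IFSRecord(n, ev))
    return IFSCurve(ClassifierSpec("knn"), records, step=1, cv_folds=2, seed=0)


def test_build_subsets_definition_and_cap():
    r3 = _ranked(["f1", "f2", "f3"])
    assert build_subsets(r3, 1) == [["f1"], ["f1", "f2"], ["f1", "f2", "f3"]]
    r5 = _ranked([f"f{i}" for i in range(1, 6)])
    assert [len(s) for s in build_subsets(r5, 2)] == [2, 4, 5]
    subsets = build_subsets(r5, 2)
    for a, b in zip(subsets, subsets[1:]):
        assert b[: len(a)] == a  # nested prefixes
    with pytest.raises(ConfigurationError):
        build_subsets(r3, 0)


@pytest.mark.parametrize("algorithm", ["random_forest", "knn", "decision_tree"])
def test_separable_data_gives_perfect_mcc(separable_matrix, algorithm):
    ev = cross_validate(separable_matrix, ["sep"], ClassifierSpec(algorithm),
                        folds=2, smote_mode="off", seed=0)
    assert ev.mcc == pytest.approx(1.0)


def test_each_cell_predicted_exactly_once(small_matrix):
    ev = cross_validate(small_matrix, small_matrix.gene_ids, ClassifierSpec("knn"),
                        folds=4, seed=1)
    assert int(ev.confusion.to_numpy().sum()) == small_matrix.n_cells


def test_permutation_null_mcc_near_zero():
    """Labels shuffled independently of expression: pooled CV MCC ~ 0."""
    mccs = []
    for seed in range(5):
        cfg = SyntheticConfig(n_classes=3, class_sizes=(20, 25, 15), n_genes=20,
                              markers_per_class=2, effect_size=2.5, dropout_rate=0.2, seed=seed)
        data, _ = generate(cfg)
        rng = np.random.default_rng(seed)
        data.labels = list(rng.permutation(data.labels))
        ev = cross_validate(data, data.gene_ids, ClassifierSpec("random_forest"),
                            folds=10, seed=seed)
        mccs.append(ev.mcc)
    assert abs(np.mean(mccs)) < 0.1


def test_curve_records_and_full_feature_consistency(small_matrix):
    from scmarkers import rank_mrmr

    ranked = rank_mrmr(small_matrix)
    curve = run_ifs(small_matrix, ranked, ClassifierSpec("knn"), step=5, folds=3,
                    smote_mode="off", seed=2)
    assert [r.n_features for r in curve.records] == [5, 10, 12]
    # determinism: identical seeds => identical curve
    again = run_ifs(small_matrix, ranked, ClassifierSpec("knn"), step=5, folds=3,
                    smote_mode="off", seed=2)
    assert [r.evaluation.mcc for r in curve.records] == [r.evaluation.mcc for r in again.records]


def test_smote_noop_on_balanced_folds():
    """On balanced data every training fold is balanced, so fold-internal
    SMOTE synthesizes nothing and both modes agree exactly."""
    cfg = SyntheticConfig(n_classes=3, class_sizes=(12, 12, 12), n_genes=15,
                          markers_per_class=2, effect_size=2.0, dropout_rate=0.0, seed=6)
    data, _ = generate(cfg)
    a = cross_validate(data, data.gene_ids, ClassifierSpec("knn"), folds=3,
                       smote_mode="off", seed=4)
    b = cross_validate(data, data.gene_ids, ClassifierSpec("knn"), folds=3,
                       smote_mode="fold_internal", seed=4)
    assert a.mcc == b.mcc and a.per_class_acc == b.per_class_acc


def test_select_optimal_tie_breaks_to_fewer_features():
    curve = _curve([(1, 0.5), (2, 0.9), (3, 0.9)])
    assert select_optimal(curve).n_features == 2
    single = _curve([(4, 0.2)])
    assert select_optimal(single).n_features == 4


def test_select_compact_delta_rule():
    curve = _curve([(100, 0.931), (500, 0.935), (1212, 0.940)])
    assert select_compact(curve, delta=0.01).n_features == 100
    assert select_compact(curve, delta=0.0).n_features == select_optimal(curve).n_features


def test_invalid_settings_rejected(small_matrix):
    with pytest.raises(ConfigurationError):
        cross_validate(small_matrix, small_matrix.gene_ids, ClassifierSpec("knn"), folds=1)
    with pytest.raises(ConfigurationError):
        cross_validate(small_matrix, small_matrix.gene_ids, ClassifierSpec("knn"),
                       smote_mode="sometimes")
    with pytest.raises(ConfigurationError):
        ClassifierSpec("svm")
    with pytest.raises(ConfigurationError):
        ClassifierSpec("knn", {"gamma": 1.0})


def test_fit_final_roundtrip_and_consistency(separable_matrix, tmp_path):
    model = fit_final(separable_matrix, ["sep"], ClassifierSpec("decision_tree"),
                      smote_mode="off", seed=0)
    preds = model.predict(separable_matrix)
    assert preds == separable_matrix.labels  # separable: training MCC 1.0

    model.save(tmp_path / "m.joblib")
    back = FittedClassifier.load(tmp_path / "m.joblib")
    assert back.predict(separable_matrix) == preds

    missing = separable_matrix.subset_genes(["noise1", "noise2"])
    with pytest.raises(ConsistencyError):
        model.predict(missing)
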