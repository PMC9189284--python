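import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from scmarkers import (
    LabelledMatrix,
    SyntheticConfig,
    ValidationError,
    discretize,
    generate,
    mutual_information,
    rank_mrmr,
)


def naive_mrmr_oracle(data, sigma=1.0):
    """Exhaustive greedy reference: re-computes every MI from scratch at every
    step with sklearn's mutual_info_score (plug-in, nats)."""
    states = {g: discretize(data.values[:, j], sigma) for j, g in enumerate(data.gene_ids)}
    labels = data.label_array()
    order_index = {g: j for j, g in enumerate(data.gene_ids)}
    relevance = {g: mutual_info_score(states[g], labels) for g in data.gene_ids}
    selected: list[str] = []
    remaining = list(data.gene_ids)
    scores = []
    while remaining:
        best, best_phi = None, None
        for g in remaining:  # ties -> lower input column index (list order)
            red = np.mean([mutual_info_score(states[g], states[s]) for s in selected]) if selected else 0.0
            phi = relevance[g] - red
            if best_phi is None or phi > best_phi + 1e-15:
                best, best_phi = g, phi
        selected.append(best)
        scores.append(best_phi)
        remaining = [g for g in remaining if g != best]
        remaining.sort(key=lambda g: order_index[g])
    return selected, scores


def test_discretize_constant_and_thresholds():
    np.testing.assert_array_equal(discretize([0.0, 0.0, 0.0, 0.0]), [1, 1, 1, 1])
    np.testing.assert_array_equal(discretize([-10.0, 0.0, 10.0], sigma=0.5), [0, 1, 2])


def test_discretize_affine_invariant():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    for a, b in [(2.5, 3.0), (0.01, -7.0), (1000.0, 0.0)]:
        np.testing.assert_array_equal(discretize(x), discretize(a * x + b))


def test_mutual_information_hand_values():
    u = np.repeat([0, 1], 50)
    assert mutual_information(u, u) == pytest.approx(np.log(2), abs=1e-12)
    rng = np.random.default_rng(0)
    a, b = rng.integers(0, 2, 10000), rng.integers(0, 2, 10000)
    assert mutual_information(a, b) < 0.01
    assert mutual_information(a, b) == pytest.approx(mutual_information(b, a), abs=1e-15)
    assert mutual_information(a, b) >= 0.0
    with pytest.raises(ValidationError):
        mutual_information([0, 1], [0])


def test_single_feature_ranking():
    data, _ = generate(SyntheticConfig(n_classes=2, class_sizes=(10, 10), n_genes=1,
                                       markers_per_class=0, dropout_rate=0.0, seed=0))
    ranked = rank_mrmr(data)
    assert ranked.gene_ids == data.gene_ids
    s = discretize(data.values[:, 0])
    assert ranked.scores[0] == pytest.approx(mutual_info_score(s, data.label_array()), abs=1e-12)


def test_first_pick_maximizes_relevance():
    data, _ = generate(SyntheticConfig(n_classes=3, class_sizes=(15, 15, 15), n_genes=20,
                                       markers_per_class=2, effect_size=3.0,
                                       dropout_rate=0.0, seed=4))
    ranked = rank_mrmr(data)
    labels = data.label_array()
    rels = [mutual_info_score(discretize(data.values[:, j]), labels)
            for j in range(data.n_genes)]
    assert ranked.gene_ids[0] == data.gene_ids[int(np.argmax(rels))]


def test_full_ranking_matches_exhaustive_oracle():
    """5-feature, 60-cell seeded instance: the incremental implementation must
    equal the from-scratch greedy re-computation at every step."""
    data, _ = generate(SyntheticConfig(n_classes=3, class_sizes=(20, 20, 20), n_genes=5,
                                       markers_per_class=1, effect_size=2.0,
                                       dropout_rate=0.1, seed=42))
    ranked = rank_mrmr(data)
    oracle_ids, oracle_scores = naive_mrmr_oracle(data)
    assert ranked.gene_ids == oracle_ids
    np.testing.assert_allclose(ranked.scores, oracle_scores, atol=1e-10)


def test_ranking_is_permutation_and_top_is_prefix():
    data, _ = generate(SyntheticConfig(n_classes=2, class_sizes=(12, 14), n_genes=15,
                                       markers_per_class=3, effect_size=2.0,
                                       dropout_rate=0.2, seed=9))
    ranked = rank_mrmr(data)
    assert sorted(ranked.gene_ids) == sorted(data.gene_ids)
    assert rank_mrmr(data, top=6).entries == ranked.entries[:6]


def test_duplicate_feature_pays_redundancy_penalty():
    """An exact copy of the top feature scores no better at selection time
    than an uncorrelated feature of equal relevance."""
    rng = np.random.default_rng(2)
    n = 120
    labels = np.repeat(["a", "b"], n // 2)
    signal = np.where(labels == "a", 1.0, 5.0) + rng.normal(0, 0.3, n)
    clone = signal.copy()
    noise = rng.normal(10, 1, n)
    data = LabelledMatrix(np.abs(np.column_stack([signal, clone, noise])),
                          [f"c{i}" for i in range(n)], ["sig", "clone", "noise"], list(labels))
    ranked = rank_mrmr(data)
    assert ranked.gene_ids[0] == "sig"
    scores = dict(ranked.entries)
    assert scores["clone"] <= scores["sig"]
    # the clone's phi is its relevance minus ~ln-scale self-MI, strictly below relevance
    assert scores["clone"] < ranked.scores[0] - 0.1


def test_markers_rank_above_noise_on_synthetic_data():
    """Mean rank of true markers is smaller than of non-markers (5 seeds)."""
    for seed in range(5):
        cfg = SyntheticConfig(n_classes=4, class_sizes=(20, 25, 30, 15), n_genes=60,
                              markers_per_class=3, effect_size=2.5, dropout_rate=0.3, seed=seed)
        data, marker_map = generate(cfg)
        markers = set().union(*marker_map.values())
        ranks = {g: i for i, g in enumerate(rank_mrmr(data).gene_ids)}
        mean_marker = np.mean([ranks[g] for g in markers])
        mean_other = np.mean([ranks[g] for g in data.gene_ids if g not in markers])
        assert mean_marker < mean_other
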