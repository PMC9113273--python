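"""Ward clustering of dynamic distances and Calinski-Harabasz model
selection, checked against brute-force re-computation oracles."""

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

from dci.community import (
    PERFECT_SEPARATION,
    ClusterSweepConfig,
    build_ward_tree,
    ch_score,
    cut_tree,
    select_communities,
)
from dci.errors import ConfigError
from dci.gnm import dynamic_distance, dynamic_distance_from_model
from dci.synthetic import make_block_correlation, make_two_domain

from conftest import random_distance_matrix
from oracles import naive_ward_features, naive_ward_lance_williams, textbook_ch_score


def partitions_of(tree, ks):
    return {
        k: {frozenset(np.flatnonzero(cut_tree(tree, k) == lab))
            for lab in range(1, k + 1)}
        for k in ks
    }


def test_two_leaves_single_merge():
    d = np.array([[0.0, 1.0], [1.0, 0.0]])
    tree = build_ward_tree(d)
    assert tree.merges.shape == (1, 4)
    assert list(cut_tree(tree, 1)) == [1, 1]
    assert list(cut_tree(tree, 2)) == [1, 2]


@pytest.mark.parametrize("mode", ["rows", "lw"])
def test_merge_sequence_matches_bruteforce_oracle(mode):
    """Every merge and every k-cut agrees with a naive Ward recomputation."""
    cfg = ClusterSweepConfig(feature_mode=mode)
    for seed in range(20):
        n = 5 + seed % 6  # 5..10 leaves
        d = random_distance_matrix(n, seed)
        tree = build_ward_tree(d, cfg)
        oracle = (
            naive_ward_features(d) if mode == "rows"
            else naive_ward_lance_williams(d)
        )
        mine = partitions_of(tree, range(1, n + 1))
        for step, partition in enumerate(oracle, start=1):
            k = n - step
            if k >= 1:
                assert mine[k] == partition, f"seed {seed} k={k} ({mode})"


def test_cut_tree_extremes_and_range():
    d = random_distance_matrix(6, 0)
    tree = build_ward_tree(d)
    assert list(cut_tree(tree, 1)) == [1] * 6
    assert sorted(cut_tree(tree, 6)) == [1, 2, 3, 4, 5, 6]
    with pytest.raises(ValueError, match="out of range"):
        cut_tree(tree, 0)
    with pytest.raises(ValueError, match="out of range"):
        cut_tree(tree, 7)


def test_cuts_are_nested():
    """The k-cut refines the (k-1)-cut of the same tree."""
    for seed in range(5):
        d = random_distance_matrix(12, seed)
        tree = build_ward_tree(d)
        parts = partitions_of(tree, range(1, 13))
        for k in range(2, 13):
            for cluster in parts[k]:
                assert any(cluster <= coarse for coarse in parts[k - 1])


def test_labels_renumbered_by_first_occurrence():
    d = random_distance_matrix(8, 4)
    labels = cut_tree(build_ward_tree(d), 3)
    seen = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    assert seen == [1, 2, 3]


def test_ch_score_matches_textbook_and_sklearn():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(10, 4))
    labels = np.array([1, 1, 2, 3, 2, 1, 3, 3, 2, 1])
    mine = ch_score(x, labels)
    assert mine == pytest.approx(textbook_ch_score(x, labels), rel=1e-12)
    assert mine == pytest.approx(calinski_harabasz_score(x, labels), rel=1e-9)


def test_ch_score_label_permutation_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(12, 3))
    labels = rng.integers(1, 4, size=12)
    while len(set(labels.tolist())) < 3:
        labels = rng.integers(1, 4, size=12)
    relabeled = np.array([{1: 3, 2: 1, 3: 2}[int(l)] for l in labels])
    assert ch_score(x, labels) == pytest.approx(ch_score(x, relabeled), rel=1e-12)


def test_ch_score_degenerate_conventions():
    # perfectly separated point masses: sentinel, not infinity or error
    x = np.array([[0.0, 0.0]] * 3 + [[5.0, 5.0]] * 3)
    labels = [1, 1, 1, 2, 2, 2]
    assert ch_score(x, labels) == PERFECT_SEPARATION
    # all points identical: 0/0 guarded to 0
    assert ch_score(np.zeros((6, 2)), labels) == 0.0
    # undefined at the sweep boundaries
    with pytest.raises(ValueError):
        ch_score(x, [1] * 6)
    with pytest.raises(ValueError):
        ch_score(x, [1, 2, 3, 4, 5, 6])


def test_block_correlation_recovered_at_true_k():
    c = make_block_correlation([5, 5], 0.9, -0.2)
    d = dynamic_distance(c)
    labels = cut_tree(build_ward_tree(d), 2)
    assert list(labels) == [1] * 5 + [2] * 5


def test_three_block_recovery_with_unequal_sizes():
    c = make_block_correlation([4, 6, 5], 0.85, -0.1)
    d = dynamic_distance(c)
    labels = cut_tree(build_ward_tree(d), 3)
    assert list(labels) == [1] * 4 + [2] * 6 + [3] * 5


def test_select_communities_on_planted_two_domain():
    fixture = make_two_domain(20, 20, gap=12.0, jitter=0.5, seed=1)
    d = dynamic_distance_from_model(fixture.model)
    result = select_communities(d)
    assert result.optimal_k == 2
    keep = np.ones(len(fixture.model), dtype=bool)
    keep[list(fixture.linker_indices)] = False
    predicted = result.optimal_labels[keep]
    planted = fixture.true_labels[keep]
    # same partition up to label names
    assert all(
        (predicted[i] == predicted[j]) == (planted[i] == planted[j])
        for i in range(len(predicted)) for j in range(i + 1, len(predicted))
    )


def test_optimal_k_is_argmax_and_ties_go_small():
    d = random_distance_matrix(30, 2)
    result = select_communities(d, ClusterSweepConfig(k_min=2, k_max=10))
    best = result.ch_by_k[result.optimal_k]
    assert all(best >= v for v in result.ch_by_k.values())
    assert all(result.optimal_k <= k
               for k, v in result.ch_by_k.items() if v == best)


def test_ranked_peaks_are_local_maxima_in_descending_order():
    d = dynamic_distance_from_model(make_two_domain(seed=3).model)
    result = select_communities(d, ClusterSweepConfig(k_min=2, k_max=12))
    scores = [s for _, s in result.ranked_peaks]
    assert scores == sorted(scores, reverse=True)
    ks = sorted(result.ch_by_k)
    for k, score in result.ranked_peaks:
        idx = ks.index(k)
        neighbours = [result.ch_by_k[ks[i]]
                      for i in (idx - 1, idx + 1) if 0 <= i < len(ks)]
        assert all(score > nb for nb in neighbours)
    assert result.ranked_peaks[0][0] == result.optimal_k


def test_sweep_requires_room_for_k_max():
    d = random_distance_matrix(10, 5)
    with pytest.raises(ConfigError, match="k_max"):
        select_communities(d, ClusterSweepConfig(k_min=2, k_max=10))
    with pytest.raises(ConfigError):
        ClusterSweepConfig(k_min=5, k_max=3)
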