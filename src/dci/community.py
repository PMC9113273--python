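"""Dynamic community detection: Ward clustering of the dynamic distance
matrix with Calinski-Harabasz model selection.

Residues are grouped by agglomerative (bottom-up) clustering with Ward's
minimum-variance criterion.  The tree is cut at every community count k in
a sweep (default 2-20) and each partition is scored with the
Calinski-Harabasz (CH) index — the ratio of between-cluster to
within-cluster dispersion, normalised by degrees of freedom:

    CH(k) = [tr(B) / (k - 1)] / [tr(W) / (N - k)]

The k with the highest CH score is the optimal community count; local
maxima of the CH-vs-k curve are reported as ranked alternative
arrangements, since a strong secondary peak often marks a biologically
meaningful finer subdivision.

Two feature interpretations of "clustering the distance matrix D" exist
and both are provided:

``rows`` (default)
    each residue is represented by its full row of D as a feature vector;
    Ward and the CH score both operate on those vectors.
``lw``
    the Ward recurrence (Lance-Williams update) is applied directly to D
    as pairwise distances; the CH score still uses rows of D as features,
    the only vector representation available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigError
from .gnm import DynamicDistanceMatrix

__all__ = [
    "ClusterSweepConfig",
    "LinkageTree",
    "CommunityResult",
    "build_ward_tree",
    "cut_tree",
    "ch_score",
    "select_communities",
]

#: Sentinel CH score for perfectly separated clusters (zero within-cluster
#: dispersion but nonzero between-cluster dispersion).
PERFECT_SEPARATION = np.finfo(float).max


@dataclass(frozen=True)
class ClusterSweepConfig:
    """Sweep settings: community counts to explore and feature interpretation."""

    k_min: int = 2
    k_max: int = 20
    feature_mode: Literal["rows", "lw"] = "rows"

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ConfigError(
                f"need 2 <= k_min <= k_max, got k_min={self.k_min} k_max={self.k_max}"
            )
        if self.feature_mode not in ("rows", "lw"):
            raise ConfigError(f"unknown feature_mode {self.feature_mode!r}")


@dataclass
class LinkageTree:
    """Agglomerative merge history in scipy linkage form.

    ``merges`` is the (N-1, 4) scipy linkage matrix: children, merge height,
    cluster size.  Heights are non-decreasing under Ward.
    """

    merges: np.ndarray
    n_leaves: int
    feature_mode: str


@dataclass
class CommunityResult:
    """Community labelings over a k sweep plus CH-based model selection.

    labels_by_k maps k to 1-based per-residue labels renumbered by first
    occurrence; ranked_peaks lists local maxima of the CH curve, best first.
    """

    labels_by_k: dict[int, np.ndarray]
    ch_by_k: dict[int, float]
    optimal_k: int
    ranked_peaks: list[tuple[int, float]]
    config: ClusterSweepConfig

    @property
    def optimal_labels(self) -> np.ndarray:
        return self.labels_by_k[self.optimal_k]


def build_ward_tree(
    d: DynamicDistanceMatrix | np.ndarray,
    cfg: ClusterSweepConfig | None = None,
) -> LinkageTree:
    """Grow the Ward merge tree over the dynamic distance matrix."""
    cfg = cfg or ClusterSweepConfig()
    matrix = d.matrix if isinstance(d, DynamicDistanceMatrix) else np.asarray(d, float)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 residues")
    if cfg.feature_mode == "rows":
        # rows of the (square, hollow) matrix are deliberately treated as
        # observation vectors here; silence scipy's well-meant warning
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", hierarchy.ClusterWarning)
            merges = hierarchy.linkage(matrix, method="ward")
    else:
        merges = hierarchy.linkage(squareform(matrix, checks=False), method="ward")
    return LinkageTree(merges=merges, n_leaves=n, feature_mode=cfg.feature_mode)


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Renumber arbitrary labels to 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Cut the merge tree into exactly k communities (labels 1..k)."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k={k} out of range [1, {tree.n_leaves}]")
    raw = hierarchy.cut_tree(tree.merges, n_clusters=k).ravel()
    labels = _relabel_first_occurrence(raw)
    if labels.max() != k:
        raise RuntimeError(f"tree cut produced {labels.max()} clusters, wanted {k}")
    return labels


def ch_score(features: np.ndarray, labels: Sequence[int]) -> float:
    """Calinski-Harabasz index of a partition of feature vectors.

    Degenerate partitions get sentinel values instead of exceptions so a
    k sweep never aborts: zero within-cluster dispersion with separated
    centroids scores :data:`PERFECT_SEPARATION`; identical points (zero
    total dispersion) score 0.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = x.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or k >= n:
        raise ValueError(f"CH score undefined for k={k} with n={n}")
    overall = x.mean(axis=0)
    within = 0.0
    between = 0.0
    for lab in uniq:
        members = x[labels == lab]
        centroid = members.mean(axis=0)
        within += float(((members - centroid) ** 2).sum())
        between += len(members) * float(((centroid - overall) ** 2).sum())
    if within == 0.0 and between == 0.0:
        return 0.0
    if within == 0.0:
        return PERFECT_SEPARATION
    return (between / (k - 1)) / (within / (n - k))


def _local_maxima(ks: list[int], scores: dict[int, float]) -> list[tuple[int, float]]:
    """Strict local maxima of the CH-vs-k curve, endpoints included."""
    peaks = []
    for i, k in enumerate(ks):
        left = scores[ks[i - 1]] if i > 0 else -np.inf
        right = scores[ks[i + 1]] if i < len(ks) - 1 else -np.inf
        if scores[k] > left and scores[k] > right:
            peaks.append((k, scores[k]))
    peaks.sort(key=lambda kv: (-kv[1], kv[0]))
    return peaks


def select_communities(
    d: DynamicDistanceMatrix | np.ndarray,
    cfg: ClusterSweepConfig | None = None,
) -> CommunityResult:
    """Sweep community counts, score each partition, pick the CH argmax.

    Ties in the argmax go to the smaller k (parsimony).  Requires
    k_max < N so every swept partition has a defined CH score.
    """
    cfg = cfg or ClusterSweepConfig()
    matrix = d.matrix if isinstance(d, DynamicDistanceMatrix) else np.asarray(d, float)
    n = matrix.shape[0]
    if n <= cfg.k_max:
        raise ConfigError(f"k_max={cfg.k_max} must be smaller than N={n}")
    tree = build_ward_tree(matrix if not isinstance(d, DynamicDistanceMatrix) else d, cfg)
    features = matrix  # rows of D, the feature representation for CH in both modes

    labels_by_k: dict[int, np.ndarray] = {}
    ch_by_k: dict[int, float] = {}
    for k in range(cfg.k_min, cfg.k_max + 1):
        labels = cut_tree(tree, k)
        labels_by_k[k] = labels
        ch_by_k[k] = ch_score(features, labels)

    ks = sorted(ch_by_k)
    optimal_k = ks[0]
    for k in ks[1:]:
        if ch_by_k[k] > ch_by_k[optimal_k]:
            optimal_k = k
    return CommunityResult(
        labels_by_k=labels_by_k,
        ch_by_k=ch_by_k,
        optimal_k=optimal_k,
        ranked_peaks=_local_maxima(ks, ch_by_k),
        config=cfg,
    )
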