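"""Independent brute-force oracles used only by tests.

These deliberately re-derive results from first principles — explicit
centroid sums, full pairwise cost recomputation each merge step — so they
share no code path with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def naive_ward_features(x: np.ndarray):
    """Ward agglomeration on feature vectors, recomputing all merge costs
    each step from raw data.

    Returns the partition after every merge as a list of sets of
    frozensets of leaf indices.  Merge cost between clusters A, B is the
    increase in total within-cluster sum of squares:
    |A||B|/(|A|+|B|) * ||centroid_A - centroid_B||^2.
    Ties break on the lexicographically smallest (min-index, max-index).
    """
    x = np.asarray(x, float)
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(x))]
    partitions = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = x[list(clusters[a])].mean(axis=0)
                cb = x[list(clusters[b])].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                cost = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                key = (cost, min(min(clusters[a]), min(clusters[b])),
                       max(min(clusters[a]), min(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        partitions.append(set(clusters))
    return partitions


def naive_ward_lance_williams(d: np.ndarray):
    """Ward agglomeration driven by the Lance-Williams recurrence on a
    pairwise distance matrix, maintained explicitly step by step.

    d(AB, C)^2 = [(a+c) d(A,C)^2 + (b+c) d(B,C)^2 - c d(A,B)^2] / (a+b+c)
    with a, b, c the cluster sizes.  Returns partitions after each merge.
    """
    d2 = np.asarray(d, float) ** 2
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(d2))]
    dist2 = {
        (i, j): d2[i, j]
        for i in range(len(d2))
        for j in range(i + 1, len(d2))
    }

    def get(i, j):
        return dist2[(i, j) if i < j else (j, i)]

    partitions = []
    active = list(range(len(clusters)))
    sizes = {i: 1 for i in active}
    next_id = len(clusters)
    members = {i: clusters[i] for i in active}
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bj in range(ai + 1, len(active)):
                i, j = active[ai], active[bj]
                cost = get(i, j)
                key = (cost, min(min(members[i]), min(members[j])),
                       max(min(members[i]), min(members[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        a, b = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        members[new] = members[i] | members[j]
        sizes[new] = a + b
        for k in active:
            if k in (i, j):
                continue
            c = sizes[k]
            dist2[(min(k, new), max(k, new))] = (
                (a + c) * get(i, k) + (b + c) * get(j, k) - c * get(i, j)
            ) / (a + b + c)
        active = [k for k in active if k not in (i, j)] + [new]
        partitions.append({members[k] for k in active})
    return partitions


def textbook_ch_score(x: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index by explicit centroid sums (no shortcuts)."""
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    n = len(x)
    uniq = sorted(set(labels.tolist()))
    k = len(uniq)
    grand = x.sum(axis=0) / n
    tr_b = 0.0
    tr_w = 0.0
    for lab in uniq:
        members = x[labels == lab]
        centroid = members.sum(axis=0) / len(members)
        tr_b += len(members) * float(((centroid - grand) ** 2).sum())
        for row in members:
            tr_w += float(((row - centroid) ** 2).sum())
    return (tr_b / (k - 1)) / (tr_w / (n - k))


def pairwise_harmonic_energy(coords: np.ndarray, pairs, rest_lengths, gamma=1.0):
    """Total energy of the pairwise harmonic (spring) potential."""
    e = 0.0
    for (i, j), r0 in zip(pairs, rest_lengths):
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e += 0.5 * gamma * (r - r0) ** 2
    return e


def finite_difference_hessian(coords: np.ndarray, cutoff: float,
                              gamma: float = 1.0, h: float = 1e-4) -> np.ndarray:
    """Numerical second derivatives of the spring potential at equilibrium."""
    n = len(coords)
    pairs = []
    rest = []
    for i in range(n):
        for j in range(i + 1, n):
            r0 = float(np.linalg.norm(coords[i] - coords[j]))
            if r0 <= cutoff:
                pairs.append((i, j))
                rest.append(r0)
    x0 = np.asarray(coords, float).ravel()

    def energy(x):
        return pairwise_harmonic_energy(x.reshape(n, 3), pairs, rest, gamma)

    dim = 3 * n
    hess = np.zeros((dim, dim))
    for p in range(dim):
        for q in range(p, dim):
            xpp = x0.copy(); xpp[p] += h; xpp[q] += h
            xpm = x0.copy(); xpm[p] += h; xpm[q] -= h
            xmp = x0.copy(); xmp[p] -= h; xmp[q] += h
            xmm = x0.copy(); xmm[p] -= h; xmm[q] -= h
            val = (energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)) / (4 * h * h)
            hess[p, q] = hess[q, p] = val
    return hess
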