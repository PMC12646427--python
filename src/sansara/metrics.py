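"""Clustering and embedding quality metrics.

Silhouette sweeps over clustering resolutions, rank-based trustworthiness /
continuity between a reference space (e.g. corrected PCA) and a 2-D map,
Jaccard cluster cross-mapping, adjusted Rand index and per-cluster pair
agreement.  All are exact, deterministic implementations; rank ties are
broken by cell index.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.special import comb
from sklearn.metrics import silhouette_samples

from .embed_cluster import ClusterLabels, Embedding

__all__ = [
    "silhouette_sweep",
    "trustworthiness",
    "continuity",
    "jaccard_cluster_map",
    "adjusted_rand",
    "per_cluster_agreement",
]

DEFAULT_METRIC_KS = (5, 15, 30)


def _coords(x) -> np.ndarray:
    return x.coords if isinstance(x, Embedding) else np.asarray(x, dtype=float)


def _labels(x) -> np.ndarray:
    return x.labels if isinstance(x, ClusterLabels) else np.asarray(x)


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def silhouette_sweep(embedding, labelings: Sequence) -> pd.DataFrame:
    """Mean silhouette per clustering, macro-averaged across clusters.

    For each labeling: per-cell silhouettes s_i = (b_i - a_i)/max(a_i, b_i)
    with Euclidean distance in ``embedding``; cluster means are averaged with
    equal cluster weight (macro average); the plain per-cell mean is reported
    alongside.  Labelings with fewer than two clusters yield NaN.  Cells in
    singleton clusters get s_i = 0.
    """
    coords = _coords(embedding)
    rows = []
    for lab in labelings:
        labels = _labels(lab)
        res = getattr(lab, "resolution", np.nan)
        k = len(np.unique(labels))
        if k < 2:
            rows.append({"resolution": res, "n_clusters": k,
                         "silhouette_macro": np.nan, "silhouette_mean": np.nan})
            continue
        s = silhouette_samples(coords, labels)
        macro = float(np.mean([s[labels == c].mean() for c in np.unique(labels)]))
        rows.append({"resolution": res, "n_clusters": k,
                     "silhouette_macro": macro, "silhouette_mean": float(s.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trustworthiness / continuity
# ---------------------------------------------------------------------------

def _rank_matrix(coords: np.ndarray) -> np.ndarray:
    """ranks[i, j] = rank of j among i's neighbors (1 = nearest), ties by index."""
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")  # stable: ties broken by index
    n = coords.shape[0]
    ranks = np.empty((n, n), dtype=np.int64)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]
    return ranks


def trustworthiness(high, low, k: int) -> float:
    """T(k) = 1 - 2/(n k (2n-3k-1)) * sum over low-space kNN intruders of (rank - k).

    Penalizes points that appear among a cell's k nearest neighbors in the
    low-dimensional space without being near it in the high-dimensional
    reference — i.e. neighbors the map invented.
    """
    xh, xl = _coords(high), _coords(low)
    n = xh.shape[0]
    if xl.shape[0] != n:
        raise ValueError(f"embeddings disagree on cell count: {n} vs {xl.shape[0]}")
    if not 1 <= k < n / 2:
        raise ValueError(f"k={k} outside the valid range [1, n/2) for n={n}")
    ranks_high = _rank_matrix(xh)
    ranks_low = _rank_matrix(xl)
    in_low = ranks_low <= k
    in_high = ranks_high <= k
    intruders = in_low & ~in_high
    penalty = (ranks_high[intruders] - k).sum()
    return float(1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty)


def continuity(high, low, k: int) -> float:
    """Symmetric counterpart of trustworthiness: penalizes true high-space
    neighbors missing from the low-space neighborhood (neighbors the map lost).
    Definitionally continuity(h, l, k) = trustworthiness(l, h, k)."""
    return trustworthiness(low, high, k)


# ---------------------------------------------------------------------------
# cluster comparison
# ---------------------------------------------------------------------------

def _contingency(a: np.ndarray, b: np.ndarray):
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table, ua, ub


def jaccard_cluster_map(labels_a, labels_b) -> pd.DataFrame:
    """J(a, b) = |a & b| / |a | b| for every pair of clusters across labelings."""
    a, b = _labels(labels_a), _labels(labels_b)
    if len(a) != len(b):
        raise ValueError(f"labelings differ in length: {len(a)} vs {len(b)}")
    table, ua, ub = _contingency(a, b)
    sizes_a = table.sum(axis=1, keepdims=True)
    sizes_b = table.sum(axis=0, keepdims=True)
    union = sizes_a + sizes_b - table
    return pd.DataFrame(table / union, index=ua, columns=ub)


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement (permutation-model ARI)."""
    a, b = _labels(labels_a), _labels(labels_b)
    if len(a) != len(b):
        raise ValueError(f"labelings differ in length: {len(a)} vs {len(b)}")
    n = len(a)
    if n < 2:
        raise ValueError("ARI needs at least 2 cells")
    table, _, _ = _contingency(a, b)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial -> perfect agreement
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def per_cluster_agreement(labels_ref, labels_other) -> pd.DataFrame:
    """Pairwise co-membership preservation between reference clusters.

    Entry (a, a') is the fraction of cell pairs drawn one from reference
    cluster a and one from a' (unordered; within-cluster pairs when a = a')
    whose co-membership relation is preserved in the other labeling: pairs
    within a cluster should stay together, pairs across clusters should stay
    apart.  Cells from an intact reference cluster give a diagonal of 1.
    Entries with no eligible pair (singleton diagonal) are 1 by convention.
    """
    ref, other = _labels(labels_ref), _labels(labels_other)
    if len(ref) != len(other):
        raise ValueError(f"labelings differ in length: {len(ref)} vs {len(other)}")
    table, ua, _ = _contingency(ref, other)  # ref clusters x other clusters
    sizes = table.sum(axis=1).astype(float)
    k = len(ua)
    out = np.ones((k, k))
    # together[a] = pairs within a kept together in `other`
    together = comb(table, 2).sum(axis=1)
    for i in range(k):
        n_pairs = sizes[i] * (sizes[i] - 1) / 2.0
        if n_pairs > 0:
            out[i, i] = together[i] / n_pairs
    # off-diagonal: pairs between a and a' kept apart
    cross_same = table @ table.T  # pairs (i in a, j in a') placed together in other
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            n_pairs = sizes[i] * sizes[j]
            out[i, j] = 1.0 - cross_same[i, j] / n_pairs
    return pd.DataFrame(out, index=ua, columns=ua)
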