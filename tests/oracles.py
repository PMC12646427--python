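"""Brute-force reference implementations used only to check the package.

Everything here is written for clarity over speed (explicit loops and pair
enumeration, O(n^2) or worse) and stays independent of the code paths it
validates.
"""

from itertools import combinations

import numpy as np


def log_normalize_bf(counts: np.ndarray, scale_factor: float = 1e4) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    out = np.zeros_like(counts)
    for i in range(counts.shape[0]):
        total = counts[i].sum()
        for j in range(counts.shape[1]):
            out[i, j] = np.log1p(counts[i, j] / total * scale_factor)
    return out


def zero_intercept_slope_bf(u, s) -> float:
    num = sum(ui * si for ui, si in zip(u, s))
    den = sum(si * si for si in s)
    return num / den if den else 0.0


def knn_pool_bf(coords: np.ndarray, values: np.ndarray, k: int) -> np.ndarray:
    """Average `values` over each point's k nearest points (self included)."""
    n = coords.shape[0]
    out = np.zeros_like(values, dtype=float)
    for i in range(n):
        d = [np.linalg.norm(coords[i] - coords[j]) for j in range(n)]
        nearest = np.argsort(d, kind="stable")[:k]
        out[i] = values[nearest].mean(axis=0)
    return out


def dispersion_bf(e: np.ndarray, n_bins: int = 20):
    """Var/mean of each column, z-scored within quantile bins of the mean."""
    import pandas as pd

    mean = e.mean(axis=0)
    var = e.var(axis=0, ddof=1)
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
    out = np.full(len(mean), -np.inf)
    ok = np.isfinite(disp) & (var > (1e-12 * np.maximum(1.0, mean)) ** 2)
    df = pd.DataFrame({"mean": mean[ok], "disp": disp[ok]})
    nb = max(1, min(n_bins, int(ok.sum()) // 10, df["mean"].nunique()))
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), nb, labels=False)
    z = np.empty(len(df))
    for b, grp in df.groupby("bin"):
        if len(grp) > 1 and grp["disp"].std(ddof=1) > 0:
            z[grp.index] = (grp["disp"] - grp["disp"].mean()) / grp["disp"].std(ddof=1)
        else:
            z[grp.index] = 0.0
    out[ok] = z
    return out


# ---------------------------------------------------------------------------
# embedding quality
# ---------------------------------------------------------------------------

def _neighbor_order_bf(x: np.ndarray, i: int):
    """Indices of all j != i ordered by (distance to i, index)."""
    others = [j for j in range(len(x)) if j != i]
    return sorted(others, key=lambda j: (np.linalg.norm(x[i] - x[j]), j))


def trustworthiness_bf(high: np.ndarray, low: np.ndarray, k: int) -> float:
    n = len(high)
    penalty = 0
    for i in range(n):
        order_high = _neighbor_order_bf(high, i)
        order_low = _neighbor_order_bf(low, i)
        rank_high = {j: r + 1 for r, j in enumerate(order_high)}
        knn_low = set(order_low[:k])
        knn_high = set(order_high[:k])
        for j in knn_low - knn_high:
            penalty += rank_high[j] - k
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty


def continuity_bf(high: np.ndarray, low: np.ndarray, k: int) -> float:
    """Penalize high-space neighbors absent from the low-space neighborhood."""
    n = len(high)
    penalty = 0
    for i in range(n):
        order_high = _neighbor_order_bf(high, i)
        order_low = _neighbor_order_bf(low, i)
        rank_low = {j: r + 1 for r, j in enumerate(order_low)}
        knn_high = set(order_high[:k])
        knn_low = set(order_low[:k])
        for j in knn_high - knn_low:
            penalty += rank_low[j] - k
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty


def silhouette_bf(x: np.ndarray, labels: np.ndarray):
    """Per-sample silhouettes by direct definition; singletons get 0."""
    n = len(x)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            s[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) - {labels[i]}
        )
        s[i] = (b - a) / max(a, b)
    return s


def silhouette_macro_bf(x: np.ndarray, labels: np.ndarray) -> float:
    s = silhouette_bf(x, labels)
    return float(np.mean([s[labels == c].mean() for c in np.unique(labels)]))


# ---------------------------------------------------------------------------
# cluster agreement
# ---------------------------------------------------------------------------

def ari_bf(a, b) -> float:
    """ARI from explicit pair counting over all cell pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i, j in combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif sa:
            n10 += 1
        elif sb:
            n01 += 1
        else:
            n00 += 1
    total = n11 + n10 + n01 + n00
    sum_a = n11 + n10
    sum_b = n11 + n01
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def jaccard_map_bf(a, b):
    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    out = np.zeros((len(ua), len(ub)))
    for i, ca in enumerate(ua):
        set_a = set(np.flatnonzero(a == ca))
        for j, cb in enumerate(ub):
            set_b = set(np.flatnonzero(b == cb))
            out[i, j] = len(set_a & set_b) / len(set_a | set_b)
    return out


def agreement_bf(ref, other):
    """Pairwise co-membership preservation; entries with no pairs are 1."""
    ref, other = np.asarray(ref), np.asarray(other)
    uref = np.unique(ref)
    k = len(uref)
    pres = np.zeros((k, k))
    count = np.zeros((k, k))
    for i, j in combinations(range(len(ref)), 2):
        a = np.flatnonzero(uref == ref[i])[0]
        b = np.flatnonzero(uref == ref[j])[0]
        same_ref = ref[i] == ref[j]
        same_other = other[i] == other[j]
        ok = 1.0 if same_ref == same_other else 0.0
        pres[a, b] += ok
        count[a, b] += 1
        if a != b:
            pres[b, a] += ok
            count[b, a] += 1
    out = np.ones((k, k))
    nonzero = count > 0
    out[nonzero] = pres[nonzero] / count[nonzero]
    return out


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def wilcoxon_exact_bf(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating group assignments.

    Uses the Mann-Whitney U statistic computed by direct pair comparison
    (ties count 1/2), independent of any rank-based shortcut.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y

    def u_stat(idx_x):
        xs = [pooled[i] for i in idx_x]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx_x]
        u = 0.0
        for xi in xs:
            for yj in ys:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    mu = n1 * n2 / 2.0
    obs = abs(u_stat(set(range(n1))) - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        if abs(u_stat(set(idx)) - mu) >= obs - 1e-9:
            hits += 1
        total += 1
    return hits / total
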