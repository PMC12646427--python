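"""Marker detection on saGEX features and on conventional expression.

The test is the two-sided Wilcoxon rank-sum per feature (exact enumeration
for small groups, tie-corrected normal approximation otherwise), with
log2 fold changes on the expm1-mean + pseudocount-1 scale and
Benjamini-Hochberg adjustment — the convention of mainstream single-cell
marker pipelines, so numbers are comparable run to run.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import false_discovery_control, mannwhitneyu, rankdata

__all__ = [
    "wilcoxon_rank_sum",
    "rank_markers",
    "rank_all_markers",
    "overlap_report",
    "dotplot_table",
]

EXACT_MAX_N = 10  # exact permutation enumeration when both groups are this small


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact when both groups have <= 10 samples.

    The exact path enumerates every assignment of the pooled observations to
    the two groups (handling ties through midranks), so it remains valid for
    heavily tied sparse expression values where the classical exact tables
    do not apply.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        mu = n1 * (n1 + n2 + 1) / 2.0
        obs = abs(ranks[:n1].sum() - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            stat = abs(ranks[list(idx)].sum() - mu)
            if stat >= obs - 1e-9:
                count += 1
            total += 1
        return count / total
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _log2fc(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """log2 of (mean expm1 + 1) ratio — assumes log1p-normalized input values."""
    return float(np.log2((np.expm1(x_in).mean() + 1.0) / (np.expm1(x_out).mean() + 1.0)))


def rank_markers(
    matrix,
    feature_names: Sequence[str],
    labels,
    group,
    reference=None,
    min_pct: float = 0.1,
    min_abs_log2fc: float = 0.25,
) -> pd.DataFrame:
    """Markers of ``group`` versus ``reference`` (default: all other cells).

    ``matrix`` holds log-normalized values, cells x features.  Features where
    neither group expresses at least ``min_pct`` of cells, or where
    |log2fc| < ``min_abs_log2fc``, are not tested (the standard prefilter;
    set both to 0 to test everything).  P-values are BH-adjusted across the
    tested features of this comparison.
    """
    dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    in_mask = labels == group
    out_mask = ~in_mask if reference is None else labels == reference
    n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
    if n_in == 0 or n_out == 0:
        raise ValueError(f"empty group in comparison {group!r} vs {reference!r}")
    if min(n_in, n_out) < 3:
        warnings.warn(f"group with fewer than 3 cells in comparison {group!r} vs {reference!r}")

    x_in = dense[in_mask]
    x_out = dense[out_mask]
    pct_in = (x_in > 0).mean(axis=0)
    pct_out = (x_out > 0).mean(axis=0)
    lfc = np.array([_log2fc(x_in[:, j], x_out[:, j]) for j in range(dense.shape[1])])

    testable = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= min_abs_log2fc)
    rows = []
    pvals = []
    for j in np.flatnonzero(testable):
        a, b = x_in[:, j], x_out[:, j]
        if np.all(a == a[0]) and np.all(b == a[0]):  # identical constant groups
            p = 1.0
        else:
            p = wilcoxon_rank_sum(a, b)
        pvals.append(p)
        rows.append({
            "feature": feature_names[j],
            "group": group,
            "log2fc": lfc[j],
            "p": p,
            "pct_in": pct_in[j],
            "pct_out": pct_out[j],
        })
    df = pd.DataFrame(rows, columns=["feature", "group", "log2fc", "p", "pct_in", "pct_out"])
    if len(df):
        df["p_adj"] = np.minimum(1.0, np.maximum(df["p"], false_discovery_control(df["p"], method="bh")))
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return df.sort_values(["p_adj", "p"], kind="stable").reset_index(drop=True)


def rank_all_markers(matrix, feature_names, labels, **kwargs) -> pd.DataFrame:
    """Each cluster versus the rest, concatenated (FindAllMarkers-style)."""
    labels = np.asarray(labels)
    parts = [
        rank_markers(matrix, feature_names, labels, group=g, **kwargs)
        for g in np.unique(labels)
    ]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def _sagex_gene(feature: str) -> str:
    return feature.rsplit(".", 1)[0] if feature.endswith((".s", ".u")) else feature


def overlap_report(
    de_sagex: pd.DataFrame,
    de_unaware: pd.DataFrame,
    lfc_threshold: float = 1.5,
    padj_threshold: float = 0.05,
    kind: Optional[str] = None,
) -> dict:
    """Genes upregulated under each analysis and their overlap.

    A gene passes when log2fc > ``lfc_threshold`` and p_adj < ``padj_threshold``.
    saGEX features ``g.s`` / ``g.u`` are mapped back to gene g; pass
    ``kind='s'`` or ``'u'`` to count only one form.  Returns counts plus the
    three gene sets {sagex_only, unaware_only, overlap}.
    """
    def passing(df, map_features):
        if df.empty:
            return set()
        hit = df[(df["log2fc"] > lfc_threshold) & (df["p_adj"] < padj_threshold)]
        feats = hit["feature"].astype(str)
        if map_features:
            if kind is not None:
                feats = feats[feats.str.endswith(f".{kind}")]
            return {_sagex_gene(f) for f in feats}
        return set(feats)

    sa = passing(de_sagex, map_features=True)
    un = passing(de_unaware, map_features=False)
    return {
        "sagex_only": sorted(sa - un),
        "unaware_only": sorted(un - sa),
        "overlap": sorted(sa & un),
        "n_sagex": len(sa),
        "n_unaware": len(un),
        "n_overlap": len(sa & un),
    }


def dotplot_table(matrix, feature_names, labels, features) -> pd.DataFrame:
    """Dot-plot quantities: per (feature, cluster) expressing fraction and
    the cluster-mean expression z-scored across clusters (ddof=1).

    Unknown features are reported in the ``missing`` attribute-style key of
    the returned frame's ``attrs`` and skipped.
    """
    dense = matrix.toarray() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    name_to_col = {f: j for j, f in enumerate(feature_names)}
    missing = [f for f in features if f not in name_to_col]
    present = [f for f in features if f in name_to_col]
    groups = np.unique(labels)
    rows = []
    for f in present:
        col = dense[:, name_to_col[f]]
        means = np.array([col[labels == g].mean() for g in groups])
        pcts = np.array([(col[labels == g] > 0).mean() for g in groups])
        sd = means.std(ddof=1) if len(groups) > 1 else 0.0
        z = (means - means.mean()) / sd if sd > 0 else np.zeros_like(means)
        for g, m, p, zz in zip(groups, means, pcts, z):
            rows.append({"feature": f, "cluster": g, "pct_expressed": p,
                         "mean": m, "scaled_mean": zz})
    out = pd.DataFrame(rows)
    out.attrs["missing_features"] = missing
    return out
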