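"""Gene selection, phase-portrait fitting and per-cell splicing scores.

The splicing score of gene g in cell c is the velocity-style residual

    v(c, g) = u_smoothed(c, g) - gamma_hat_g * s_smoothed(c, g)

where gamma_hat is the steady-state slope of unspliced on spliced counts
(zero-intercept regression restricted to the extreme quantiles of s — the
cells closest to the two steady states of the phase portrait).  A positive
score means the cell holds more unspliced molecules than the gene's steady
state predicts; negative means a spliced-form excess.  This deterministic
estimator replaces probabilistic velocity fits so results are exactly
reproducible on one CPU; the interface is estimator-agnostic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_counts import SplicedUnsplicedMatrix
from .sagex import log_normalize

__all__ = [
    "PhasePortraitFit",
    "PooledLayers",
    "ScoreMatrix",
    "select_hvg",
    "pool_neighbors",
    "fit_phase_portrait",
    "fit_all_genes",
    "compute_scores",
]

#: T-cell receptor segment genes are excluded from variable-gene selection:
#: their clonal expression would otherwise dominate the feature space.
DEFAULT_EXCLUDE_PATTERNS = (r"^TR[ABGD][VDJC]",)


@dataclass
class PhasePortraitFit:
    """Zero-intercept steady-state fit of one gene's phase portrait.

    A gene fails QC when either the quantile-restricted slope (gamma_hat) or
    the unrestricted all-cell slope is zero — such genes are too poorly
    detected for splicing estimation.
    """

    gene_id: str
    gamma_hat: float
    r2: float
    n_support: int
    passed_qc: bool
    slope_all: float = 0.0


@dataclass
class PooledLayers:
    """kNN-smoothed unspliced/spliced layers (dense, cells x genes)."""

    u: np.ndarray
    s: np.ndarray
    gene_ids: list
    barcodes: list
    k: int = 1


@dataclass
class ScoreMatrix:
    """Signed per-cell, per-gene splicing scores for QC-passed genes.

    Sign convention: positive = unspliced predominance, negative = spliced.
    With ``scaling='maxabs'`` every gene column is divided by its maximum
    absolute value, so columns lie in [-1, 1] (all-zero columns stay zero).
    """

    values: np.ndarray
    gene_ids: list
    barcodes: list
    scaling: str = "none"


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

def standardized_dispersion(e_dense: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Dispersion (var/mean) of log-normalized values, z-scored within mean bins.

    Genes with zero mean get -inf so they always rank last.  Bins are
    quantile bins over per-gene means; a bin with a single gene (or zero
    spread) contributes standardized dispersion 0 for its genes.
    """
    mean = e_dense.mean(axis=0)
    var = e_dense.var(axis=0, ddof=1) if e_dense.shape[0] > 1 else np.zeros(e_dense.shape[1])
    # variance of a constant column is ~ (eps*value)^2, not exactly 0
    effectively_constant = var <= (1e-12 * np.maximum(1.0, mean)) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    out = np.full(mean.shape, -np.inf)
    ok = np.isfinite(disp) & ~effectively_constant
    if ok.sum() == 0:
        return out
    df = pd.DataFrame({"mean": mean[ok], "disp": disp[ok]})
    # bins need enough genes each for a meaningful within-bin z-score
    n_bins_eff = max(1, min(n_bins, int(ok.sum()) // 10, df["mean"].nunique()))
    df["bin"] = pd.qcut(df["mean"].rank(method="first"), n_bins_eff, labels=False)
    z = df.groupby("bin")["disp"].transform(
        lambda x: (x - x.mean()) / x.std(ddof=1) if len(x) > 1 and x.std(ddof=1) > 0 else 0.0 * x
    )
    out[ok] = z.to_numpy()
    return out


def select_hvg(
    m: SplicedUnsplicedMatrix,
    n_top: int = 2000,
    exclude_patterns: Sequence[str] = DEFAULT_EXCLUDE_PATTERNS,
) -> list:
    """Top-``n_top`` genes by standardized dispersion of log-normalized totals.

    Genes whose *name* matches any of ``exclude_patterns`` (default: TCR
    V/D/J/C segment genes) are removed before ranking.  If fewer genes than
    ``n_top`` remain, all are returned with a warning.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    regexes = [re.compile(p) for p in (exclude_patterns or ())]
    keep_idx = [
        i for i, name in enumerate(m.gene_names)
        if not any(r.search(str(name)) for r in regexes)
    ]
    e = log_normalize(m)
    disp = standardized_dispersion(e.e.toarray())
    keep_idx = np.asarray(keep_idx, dtype=int)
    order = keep_idx[np.argsort(-disp[keep_idx], kind="stable")]
    if n_top > len(order):
        warnings.warn(
            f"requested {n_top} variable genes but only {len(order)} genes are "
            "available after exclusions; returning all"
        )
        n_top = len(order)
    return [m.gene_ids[i] for i in order[:n_top]]


# ---------------------------------------------------------------------------
# neighbor pooling
# ---------------------------------------------------------------------------

def pool_neighbors(
    m: SplicedUnsplicedMatrix,
    genes: Sequence,
    k: int = 30,
    n_comps: int = 30,
    random_state: int = 0,
) -> PooledLayers:
    """Replace each cell's u/s by the mean over its k nearest cells (self included).

    Neighbors are found by Euclidean distance in PCA space (``n_comps``
    components or fewer) of the log-normalized total counts over all genes.
    ``k=1`` is the identity transform.  Raw per-cell counts are usually too
    sparse to place a cell on the phase portrait; pooling trades variance for
    a mild smoothing bias.  Note it assumes cells nearby in total-expression
    space share splicing state — for data where splicing varies independently
    of expression, use small k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({m.n_cells})")
    gene_idx = [m.gene_ids.index(g) for g in genes]
    u = m.unspliced[:, gene_idx].toarray().astype(float)
    s = m.spliced[:, gene_idx].toarray().astype(float)

    if k == 1:
        u_sm, s_sm = u, s
    else:
        e = log_normalize(m).e.toarray()
        n_comps = min(n_comps, m.n_cells - 1, e.shape[1])
        coords = PCA(n_components=n_comps, svd_solver="full", random_state=random_state).fit_transform(e)
        nn = NearestNeighbors(n_neighbors=k).fit(coords)
        idx = nn.kneighbors(coords, return_distance=False)
        u_sm = u[idx].mean(axis=1)
        s_sm = s[idx].mean(axis=1)

    return PooledLayers(u=u_sm, s=s_sm, gene_ids=list(genes), barcodes=list(m.barcodes), k=k)


# ---------------------------------------------------------------------------
# phase portrait fitting
# ---------------------------------------------------------------------------

def _zero_intercept_slope(u: np.ndarray, s: np.ndarray) -> float:
    ss = float(np.dot(s, s))
    if ss == 0.0:
        return 0.0
    return float(np.dot(u, s) / ss)


def fit_phase_portrait(
    u: np.ndarray,
    s: np.ndarray,
    quantile: float = 0.05,
    gene_id: str = "",
) -> PhasePortraitFit:
    """Steady-state slope of u on s from the extreme quantiles of s.

    Cells in the bottom and top ``quantile`` fraction of s (the presumed
    steady-state cells) enter a zero-intercept least-squares fit; the slope
    is gamma_hat = sum(u*s)/sum(s^2) over those cells.  The unrestricted
    slope over all cells is kept for the QC rule: a gene is discarded
    (``passed_qc=False``) when either slope is zero.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape != s.shape:
        raise ValueError(f"u and s differ in length: {u.shape} vs {s.shape}")
    if not 0.0 < quantile <= 0.5:
        raise ValueError(f"quantile {quantile} outside (0, 0.5]")

    slope_all = _zero_intercept_slope(u, s)
    lo, hi = np.quantile(s, [quantile, 1.0 - quantile])
    mask = (s <= lo) | (s >= hi)
    u_fit, s_fit = u[mask], s[mask]
    gamma_hat = _zero_intercept_slope(u_fit, s_fit)

    uu = float(np.dot(u_fit, u_fit))
    us = float(np.dot(u_fit, s_fit))
    ss = float(np.dot(s_fit, s_fit))
    r2 = (us * us) / (uu * ss) if uu > 0 and ss > 0 else 0.0

    return PhasePortraitFit(
        gene_id=gene_id,
        gamma_hat=gamma_hat,
        r2=r2,
        n_support=int(mask.sum()),
        passed_qc=bool(gamma_hat != 0.0 and slope_all != 0.0),
        slope_all=slope_all,
    )


def fit_all_genes(pooled: PooledLayers, quantile: float = 0.05) -> list:
    """Phase-portrait fit for every pooled gene, in gene order."""
    return [
        fit_phase_portrait(pooled.u[:, j], pooled.s[:, j], quantile=quantile, gene_id=g)
        for j, g in enumerate(pooled.gene_ids)
    ]


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def compute_scores(
    pooled: PooledLayers,
    fits: Sequence[PhasePortraitFit],
    scale_scores: bool = True,
) -> ScoreMatrix:
    """v(c,g) = u_smoothed - gamma_hat * s_smoothed for QC-passed genes.

    Positive values mark unspliced predominance, negative spliced — the sign
    encodes which form of the gene the cell favours.  With
    ``scale_scores=True`` each gene column is rescaled by its max |v| so no
    single gene's velocity magnitude dominates downstream products.
    """
    gene_pos = {g: j for j, g in enumerate(pooled.gene_ids)}
    kept = [f for f in fits if f.passed_qc]
    missing = [f.gene_id for f in kept if f.gene_id not in gene_pos]
    if missing:
        raise KeyError(f"fit genes absent from pooled layers: {missing[:5]}")

    cols = [gene_pos[f.gene_id] for f in kept]
    gammas = np.array([f.gamma_hat for f in kept])
    v = pooled.u[:, cols] - gammas[None, :] * pooled.s[:, cols]

    scaling = "none"
    if scale_scores:
        scaling = "maxabs"
        amax = np.abs(v).max(axis=0)
        nz = amax > 0
        v[:, nz] = v[:, nz] / amax[nz]

    return ScoreMatrix(
        values=v,
        gene_ids=[f.gene_id for f in kept],
        barcodes=list(pooled.barcodes),
        scaling=scaling,
    )
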