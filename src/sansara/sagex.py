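"""Build the splicing-adjusted expression matrix (saGEX).

The pipeline: log-normalize total counts, multiply per cell and gene by the
signed splicing score, then split by sign into a "spliced" feature (negative
scores, absolute value taken) and an "unspliced" feature (positive scores).
The resulting non-negative matrix has two mutually exclusive features per
gene and feeds the conventional scale/PCA/cluster pipeline unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_counts import SaGEXMatrix, SplicedUnsplicedMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedExpression",
    "log_normalize",
    "build_sagex",
    "sagex_log_normalize",
    "distribution_diagnostics",
]

DEFAULT_SCALE_FACTOR = 1e4


@dataclass
class NormalizedExpression:
    """log1p(count / cell_total * scale_factor), zero iff the count is zero."""

    e: sp.csr_matrix
    gene_ids: list
    barcodes: list
    scale_factor: float = DEFAULT_SCALE_FACTOR

    @property
    def n_cells(self) -> int:
        return self.e.shape[0]


def _normalize_csr(values: sp.csr_matrix, totals: np.ndarray, scale_factor: float) -> sp.csr_matrix:
    out = values.tocsr().astype(float).copy()
    row_scale = scale_factor / totals
    # scale each row's data in place, then log1p
    reps = np.diff(out.indptr)
    out.data *= np.repeat(row_scale, reps)
    out.data = np.log1p(out.data)
    return out


def log_normalize(
    m,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    genes: Optional[Sequence] = None,
) -> NormalizedExpression:
    """Per-cell library-size log-normalization of TOTAL (spliced+unspliced) counts.

    ``m`` may be a :class:`SplicedUnsplicedMatrix` (totals are formed first)
    or a bare sparse counts matrix plus implicit gene order.  Cell totals are
    always computed over *all* genes before any subsetting, so restricting to
    a gene panel does not change the normalization.
    """
    if isinstance(m, SplicedUnsplicedMatrix):
        counts = m.totals()
        gene_ids = list(m.gene_ids)
        barcodes = list(m.barcodes)
    else:
        counts = m.tocsr() if sp.issparse(m) else sp.csr_matrix(np.asarray(m))
        gene_ids = [f"g{i}" for i in range(counts.shape[1])]
        barcodes = [f"c{i}" for i in range(counts.shape[0])]

    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [barcodes[i] for i in zero[:10]]
        raise ValueError(
            f"{zero.size} cells have zero total counts (e.g. {bad}); "
            "filter them before normalization"
        )
    e = _normalize_csr(counts, totals, scale_factor)
    if genes is not None:
        idx = [gene_ids.index(g) for g in genes]
        e = e[:, idx].tocsr()
        gene_ids = list(genes)
    return NormalizedExpression(e=e, gene_ids=gene_ids, barcodes=barcodes, scale_factor=scale_factor)


def build_sagex(e: NormalizedExpression, v: "ScoreMatrix") -> SaGEXMatrix:
    """Multiply expression by splicing score and sign-split into g.s / g.u.

    raw(c,g) = e(c,g) * v(c,g); negative raw values become the spliced
    feature ``g.s`` (absolute value), positive become the unspliced feature
    ``g.u``.  A zero score yields zero in both features.
    """
    missing = [g for g in v.gene_ids if g not in set(e.gene_ids)]
    if missing:
        raise ValueError(f"score genes absent from expression matrix: {missing[:5]}")
    if v.values.shape[0] != e.n_cells:
        raise ValueError(
            f"cell count mismatch: expression {e.n_cells} vs scores {v.values.shape[0]}"
        )
    idx = [e.gene_ids.index(g) for g in v.gene_ids]
    e_sub = e.e[:, idx].toarray()
    raw = e_sub * v.values

    n, g = raw.shape
    out = np.zeros((n, 2 * g))
    out[:, 0::2] = np.where(raw < 0, -raw, 0.0)  # spliced form
    out[:, 1::2] = np.where(raw > 0, raw, 0.0)   # unspliced form
    feature_names = []
    for gid in v.gene_ids:
        feature_names.extend([f"{gid}.s", f"{gid}.u"])
    return SaGEXMatrix(
        values=sp.csr_matrix(out),
        feature_names=feature_names,
        barcodes=list(e.barcodes),
        gene_ids=list(v.gene_ids),
        provenance={
            "genes": list(v.gene_ids),
            "score_scaling": v.scaling,
            "scale_factor": e.scale_factor,
        },
    )


def sagex_log_normalize(m: SaGEXMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR) -> SaGEXMatrix:
    """Library-size log-normalization applied to saGEX values as pseudo-counts.

    Cells whose saGEX row is entirely zero (no net splicing signal on any
    retained gene) cannot be normalized; they are dropped with a warning and
    recorded in ``provenance['dropped_barcodes']``.
    """
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    keep = totals > 0
    dropped = [m.barcodes[i] for i in np.flatnonzero(~keep)]
    if dropped:
        logger.warning(
            "sagex_log_normalize: dropping %d all-zero cells (e.g. %s)",
            len(dropped), dropped[:5],
        )
    vals = m.values[keep]
    e = _normalize_csr(vals, totals[keep], scale_factor)
    prov = dict(m.provenance)
    prov["dropped_barcodes"] = dropped
    prov["sagex_scale_factor"] = scale_factor
    return SaGEXMatrix(
        values=e,
        feature_names=list(m.feature_names),
        barcodes=[b for b, k in zip(m.barcodes, keep) if k],
        gene_ids=list(m.gene_ids),
        provenance=prov,
    )


def distribution_diagnostics(gex, sagex, n_bins: int = 100) -> dict:
    """Per-feature moments and pooled value histograms for GEX vs saGEX.

    Accepts a :class:`NormalizedExpression` and a :class:`SaGEXMatrix` (or any
    objects exposing sparse ``e``/``values`` plus feature names).  Returns
    {'features': DataFrame, 'histogram': DataFrame}; the histogram uses one
    fixed ``n_bins``-bin grid spanning both matrices.
    """
    entries = []
    for matrix_id, mat, names in (
        ("gex", getattr(gex, "e", None), getattr(gex, "gene_ids", None)),
        ("sagex", getattr(sagex, "values", None), getattr(sagex, "feature_names", None)),
    ):
        dense = mat.toarray() if sp.issparse(mat) else np.asarray(mat)
        nz_mask = dense != 0
        nnz = nz_mask.sum(axis=0)
        mean = dense.mean(axis=0)
        var = dense.var(axis=0, ddof=1) if dense.shape[0] > 1 else np.zeros(dense.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            nz_mean = np.where(nnz > 0, dense.sum(axis=0) / np.maximum(nnz, 1), np.nan)
        nz_var = np.full(dense.shape[1], np.nan)
        for j in np.flatnonzero(nnz > 1):
            nz_var[j] = dense[nz_mask[:, j], j].var(ddof=1)
        entries.append(pd.DataFrame({
            "matrix": matrix_id,
            "feature": list(names),
            "mean": mean,
            "variance": var,
            "pct_nonzero": nnz / dense.shape[0],
            "nonzero_mean": nz_mean,
            "nonzero_variance": nz_var,
        }))
    features = pd.concat(entries, ignore_index=True)

    all_vals = [np.asarray((m.e if hasattr(m, "e") else m.values).todense()).ravel()
                for m in (gex, sagex)]
    lo = min(v.min() for v in all_vals)
    hi = max(v.max() for v in all_vals)
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    hist_rows = []
    for matrix_id, v in zip(("gex", "sagex"), all_vals):
        counts, _ = np.histogram(v, bins=edges)
        hist_rows.append(pd.DataFrame({
            "matrix": matrix_id,
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
        }))
    return {"features": features, "histogram": pd.concat(hist_rows, ignore_index=True)}
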