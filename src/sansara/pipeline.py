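"""End-to-end orchestration: the splicing-aware track and the conventional track.

Both tracks run the identical scale/PCA/SNN/cluster machinery with the same
parameters; they differ only in the feature matrix fed in — log-normalized
total counts ("gex") versus the score-adjusted, sign-split saGEX features
("sagex").  Every comparison downstream is therefore paired.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .diffexpr import overlap_report, rank_all_markers
from .embed_cluster import Embedding, batch_correct, map2d, pca, scale_features, snn_cluster
from .io_counts import SplicedUnsplicedMatrix, write_sagex
from .metrics import adjusted_rand, continuity, jaccard_cluster_map, silhouette_sweep, trustworthiness
from .sagex import build_sagex, log_normalize, sagex_log_normalize
from .scoring import compute_scores, fit_all_genes, pool_neighbors, select_hvg
from .synthetic_data import read_labels, simulate_matched_expression_pair, write_fixture

logger = logging.getLogger(__name__)

__all__ = ["TrackResult", "sagex_features", "run_track", "run_all"]


@dataclass
class TrackResult:
    """One track's embeddings and clusterings plus the features that fed them."""

    name: str
    feature_matrix: object  # cells x features, sparse or dense
    feature_names: list
    barcodes: list
    embedding: Embedding = None
    corrected: Embedding = None
    labelings: list = field(default_factory=list)
    map_2d: Optional[Embedding] = None

    def labels_at(self, resolution: float):
        for lab in self.labelings:
            if lab.resolution == resolution:
                return lab
        raise KeyError(f"no clustering at resolution {resolution}")


def sagex_features(m: SplicedUnsplicedMatrix, cfg: RunConfig):
    """HVG selection -> pooling -> phase-portrait QC -> scores -> saGEX.

    Returns (SaGEXMatrix, fits, hvg_gene_ids).  The saGEX matrix is
    re-log-normalized when ``cfg.renormalize_sagex`` is set (cells with no
    splicing signal anywhere are dropped at that step).
    """
    hvg = select_hvg(m, n_top=cfg.n_top_hvg, exclude_patterns=cfg.exclude_patterns)
    pooled = pool_neighbors(m, hvg, k=cfg.knn_k, random_state=cfg.seed)
    # the steady-state slope is a global per-gene parameter: fit it on
    # heavily pooled layers so Poisson noise in s does not attenuate the
    # quantile-restricted regression (scores keep their own, lighter pooling)
    k_gamma = min(max(cfg.gamma_pool_k, cfg.knn_k), m.n_cells)
    pooled_gamma = (
        pooled if k_gamma == cfg.knn_k
        else pool_neighbors(m, hvg, k=k_gamma, random_state=cfg.seed)
    )
    fits = fit_all_genes(pooled_gamma, quantile=cfg.fit_quantile)
    n_pass = sum(f.passed_qc for f in fits)
    logger.info("phase-portrait QC: %d/%d genes retained", n_pass, len(fits))
    if n_pass == 0:
        raise ValueError("no gene passed phase-portrait QC; cannot build saGEX")
    scores = compute_scores(pooled, fits, scale_scores=cfg.scale_scores)
    e = log_normalize(m, scale_factor=cfg.scale_factor)
    sx = build_sagex(e, scores)
    if cfg.renormalize_sagex:
        sx = sagex_log_normalize(sx, scale_factor=cfg.scale_factor)
    return sx, fits, hvg


def run_track(
    name: str,
    features,
    feature_names,
    barcodes,
    cfg: RunConfig,
    batch=None,
    batch_hook=None,
    make_map: Optional[bool] = None,
) -> TrackResult:
    """Scale -> PCA -> (hook) -> SNN/Leiden sweep -> optional 2-D map."""
    scaled = scale_features(features)
    emb = pca(scaled, n_pcs=cfg.n_pcs, random_state=cfg.seed)
    hook = batch_hook if cfg.batch_method != "none" else None
    corrected = batch_correct(emb, batch_labels=batch, method_hook=hook, n_keep=cfg.n_pcs_used)
    labelings = snn_cluster(
        corrected, k=cfg.cluster_k, resolutions=cfg.resolutions,
        seed=cfg.seed, prune=cfg.snn_prune,
    )
    res = TrackResult(
        name=name, feature_matrix=features, feature_names=list(feature_names),
        barcodes=list(barcodes), embedding=emb, corrected=corrected, labelings=labelings,
    )
    if make_map is None:
        make_map = cfg.make_map
    if make_map:
        res.map_2d = map2d(corrected, seed=cfg.seed)
    return res


def _align_cells(track: TrackResult, barcodes) -> np.ndarray:
    """Indices of ``track.barcodes`` within the full barcode list."""
    pos = {b: i for i, b in enumerate(barcodes)}
    return np.array([pos[b] for b in track.barcodes])


def run_all(cfg: RunConfig, outdir, true_labels=None, matrix: Optional[SplicedUnsplicedMatrix] = None) -> dict:
    """Full dual-track run; writes TSV outputs plus a provenance manifest.

    Input priority: explicit ``matrix`` argument, then ``cfg.input_dir``,
    otherwise the matched-expression-pair simulation described by the config.
    Returns a dict with both :class:`TrackResult` objects and the comparison
    tables.
    """
    cfg.validate()
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- input -------------------------------------------------------
    if matrix is None:
        if cfg.input_dir:
            from .io_counts import read_pair

            matrix = read_pair(cfg.input_dir)
            labels_path = Path(cfg.input_dir) / "labels.tsv"
            if true_labels is None and labels_path.exists():
                true_labels = read_labels(cfg.input_dir)
        else:
            matrix, true_labels = simulate_matched_expression_pair(
                n_cells_per_pop=cfg.n_cells_per_pop,
                n_genes=cfg.n_genes,
                splice_shift=cfg.splice_shift,
                seed=cfg.seed,
                n_designated=cfg.n_designated,
                depth_sigma=cfg.depth_sigma,
                dropout_rate=cfg.dropout_rate,
            )
            write_fixture(matrix, true_labels, out / "simulated")

    # ---- splicing-aware features --------------------------------------
    sx, fits, hvg = sagex_features(matrix, cfg)
    write_sagex(sx, out / "sagex")
    fits_df = pd.DataFrame([
        {"gene_id": f.gene_id, "gamma_hat": f.gamma_hat, "slope_all": f.slope_all,
         "r2": f.r2, "n_support": f.n_support, "passed_qc": f.passed_qc}
        for f in fits
    ])
    fits_df.to_csv(out / "phase_portrait_fits.tsv", sep="\t", index=False)

    # ---- conventional features ---------------------------------------
    e = log_normalize(matrix, scale_factor=cfg.scale_factor, genes=hvg)

    # ---- dual tracks --------------------------------------------------
    track_sagex = run_track("sagex", sx.values, sx.feature_names, sx.barcodes, cfg,
                            batch=matrix.batch)
    track_gex = run_track("gex", e.e, e.gene_ids, e.barcodes, cfg, batch=matrix.batch)

    for tr in (track_sagex, track_gex):
        lab_df = pd.DataFrame({"barcode": tr.barcodes})
        for lab in tr.labelings:
            lab_df[f"res_{lab.resolution:g}"] = lab.labels
        lab_df.to_csv(out / f"clusters_{tr.name}.tsv", sep="\t", index=False)
        emb_df = pd.DataFrame(
            tr.corrected.coords, index=tr.barcodes,
            columns=[f"PC{i+1}" for i in range(tr.corrected.coords.shape[1])],
        )
        emb_df.to_csv(out / f"embedding_{tr.name}.tsv", sep="\t")
        if tr.map_2d is not None:
            pd.DataFrame(tr.map_2d.coords, index=tr.barcodes, columns=["x", "y"]).to_csv(
                out / f"map2d_{tr.name}.tsv", sep="\t"
            )

    # ---- metrics -------------------------------------------------------
    metric_rows = []
    for tr in (track_sagex, track_gex):
        sil = silhouette_sweep(tr.corrected, tr.labelings)
        for _, row in sil.iterrows():
            metric_rows.append({"matrix_id": tr.name, "metric": "silhouette_macro",
                                "key": row["resolution"], "value": row["silhouette_macro"]})
            metric_rows.append({"matrix_id": tr.name, "metric": "n_clusters",
                                "key": row["resolution"], "value": row["n_clusters"]})
        if tr.map_2d is not None:
            for k in cfg.metric_ks:
                if k < tr.corrected.n_cells / 2:
                    metric_rows.append({"matrix_id": tr.name, "metric": "trustworthiness",
                                        "key": k, "value": trustworthiness(tr.corrected, tr.map_2d, k)})
                    metric_rows.append({"matrix_id": tr.name, "metric": "continuity",
                                        "key": k, "value": continuity(tr.corrected, tr.map_2d, k)})

    # paired comparisons on the cell intersection
    common = sorted(set(track_sagex.barcodes) & set(track_gex.barcodes),
                    key=track_gex.barcodes.index)
    idx_sx = {b: i for i, b in enumerate(track_sagex.barcodes)}
    idx_gx = {b: i for i, b in enumerate(track_gex.barcodes)}
    sel_sx = np.array([idx_sx[b] for b in common])
    sel_gx = np.array([idx_gx[b] for b in common])
    for res in cfg.resolutions:
        la = track_sagex.labels_at(res).labels[sel_sx]
        lb = track_gex.labels_at(res).labels[sel_gx]
        metric_rows.append({"matrix_id": "sagex_vs_gex", "metric": "ari",
                            "key": res, "value": adjusted_rand(la, lb)})
    if true_labels is not None:
        truth = np.asarray(true_labels)
        pos = {b: i for i, b in enumerate(matrix.barcodes)}
        for tr in (track_sagex, track_gex):
            sel = np.array([pos[b] for b in tr.barcodes])
            for res in cfg.resolutions:
                metric_rows.append({
                    "matrix_id": tr.name, "metric": "ari_vs_truth", "key": res,
                    "value": adjusted_rand(tr.labels_at(res).labels, truth[sel]),
                })
    pd.DataFrame(metric_rows).to_csv(out / "metrics.tsv", sep="\t", index=False)

    jac = jaccard_cluster_map(
        track_sagex.labels_at(cfg.de_resolution).labels[sel_sx],
        track_gex.labels_at(cfg.de_resolution).labels[sel_gx],
    )
    jac.to_csv(out / "jaccard_map.tsv", sep="\t")

    # ---- differential expression ---------------------------------------
    # grouping: splicing-aware clustering at the DE resolution, applied to
    # both matrices on the shared cells
    groups = track_sagex.labels_at(cfg.de_resolution).labels[sel_sx]
    de_sagex = rank_all_markers(
        track_sagex.feature_matrix[sel_sx], track_sagex.feature_names, groups,
        min_pct=cfg.de_min_pct, min_abs_log2fc=cfg.de_min_log2fc,
    )
    de_gex = rank_all_markers(
        track_gex.feature_matrix[sel_gx], track_gex.feature_names, groups,
        min_pct=cfg.de_min_pct, min_abs_log2fc=cfg.de_min_log2fc,
    )
    de_sagex.to_csv(out / "de_sagex.tsv", sep="\t", index=False)
    de_gex.to_csv(out / "de_gex.tsv", sep="\t", index=False)

    overlap_rows = []
    for g in np.unique(groups):
        rep = overlap_report(
            de_sagex[de_sagex["group"] == g], de_gex[de_gex["group"] == g],
            lfc_threshold=cfg.de_lfc_threshold, padj_threshold=cfg.de_padj_threshold,
        )
        overlap_rows.append({
            "group": g, "n_sagex": rep["n_sagex"], "n_unaware": rep["n_unaware"],
            "n_overlap": rep["n_overlap"],
            "sagex_only": ",".join(rep["sagex_only"]),
            "unaware_only": ",".join(rep["unaware_only"]),
            "overlap": ",".join(rep["overlap"]),
        })
    pd.DataFrame(overlap_rows).to_csv(out / "de_overlap.tsv", sep="\t", index=False)

    # ---- manifest -------------------------------------------------------
    cfg.write_yaml(out / "config.yaml")
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "n_cells": matrix.n_cells,
        "n_genes": matrix.n_genes,
        "n_hvg": len(hvg),
        "n_qc_genes": int(sum(f.passed_qc for f in fits)),
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {
        "matrix": matrix,
        "true_labels": true_labels,
        "sagex": sx,
        "fits": fits,
        "hvg": hvg,
        "tracks": {"sagex": track_sagex, "gex": track_gex},
        "de": {"sagex": de_sagex, "gex": de_gex},
        "manifest": manifest,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]
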