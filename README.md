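# sansara

Splicing-aware single-cell RNA-seq analysis.

Velocyto-style pipelines classify every UMI as **spliced** (mature mRNA) or
**unspliced** (intron-containing pre-mRNA). Stable cell subsets can match
each other in total expression of a gene while differing sharply in this
spliced/unspliced balance — a stored-mRNA reservoir, or pre-mRNA poised for
rapid maturation. Conventional expression analysis cannot see that axis.
`sansara` builds it into the feature matrix: for each gene g and cell c it
computes a signed splicing score

    v(c, g) = u(c, g) − γ̂_g · s(c, g)

(the residual from the gene's steady-state phase-portrait slope γ̂, fitted by
quantile-restricted regression of unspliced on spliced counts), multiplies it
by the log-normalized expression e(c, g), and splits the product by sign into
two non-negative, mutually exclusive features per gene:

    g.s = |e·v|  where v < 0   (spliced excess)
    g.u =  e·v   where v > 0   (unspliced excess)

This **splicing-adjusted expression matrix (saGEX)** then flows through the
ordinary single-cell pipeline — scaling, PCA (50 components, top 25 used),
SNN-graph Leiden clustering over a resolution sweep, UMAP — run side by side
with the conventional matrix under identical parameters, plus the comparison
metrics (silhouette sweep, trustworthiness/continuity, Jaccard cluster map,
adjusted Rand index) and Wilcoxon marker detection on both tracks.

The package is aimed at transcriptomics analysts who already have
velocyto/CellRanger-style paired count matrices (`spliced.mtx`,
`unspliced.mtx`, `features.tsv`, `barcodes.tsv`) and want to ask whether any
of their subsets differ in splicing state rather than in expression. A
kinetics simulator (two-compartment model: transcription α, splicing β,
degradation γ; Poisson sampling at the fixed point u* = α/β, s* = α/γ) makes
the whole pipeline testable without any external data.

## Worked example

Simulate two 500-cell populations over 200 genes in which 50 designated
genes have **identical expected total expression** but spliced fractions of
0.8 vs 0.2 (`splice_shift = 0.6`), then run both tracks. Pooling is
disabled (`knn_k: 1`) because in this world total expression carries no
population structure, so expression-neighborhood smoothing would average
the splicing signal away (see `docs/methods.md`):

```
$ printf 'knn_k: 1\nn_cells_per_pop: 500\nn_genes: 200\nn_designated: 50\n' > demo.yaml
$ sansara run-all --config demo.yaml --seed 0 --outdir demo
run-all complete: 1000 cells, 200 variable genes, 200 QC-passed, outputs in demo
```

`demo/metrics.tsv` (selected rows, resolution 1.0):

```
matrix_id  metric            key  value
sagex      ari_vs_truth      1.0  1.000000
gex        ari_vs_truth      1.0  0.000463
sagex      silhouette_macro  1.0  0.426513
gex        silhouette_macro  1.0  -0.039065
```

The splicing-aware track recovers the planted populations exactly
(ARI 1.0 against the true labels, two clean clusters), while the
conventional track — which sees only total expression, identical across
populations by construction — clusters at chance (ARI ≈ 0). The marker
overlap report (`demo/de_overlap.tsv`) makes the same point per gene:

```
group  n_sagex  n_unaware  n_overlap
0      50       0          0
1      50       0          0
```

All 50 designated genes pass log2FC > 1.5 (adjusted p < 0.05) on their
dominant saGEX feature in each cluster; none passes on conventional
expression, and the two analyses overlap on nothing — the designated
biology is invisible without the splicing axis.

Each run directory also contains the per-gene phase-portrait fits and QC
(`phase_portrait_fits.tsv`), per-resolution cluster labels and embeddings
for both tracks, the saGEX matrix in MatrixMarket form, full DE tables, and
a `manifest.json` with the config and output checksums for reproducibility.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end demonstration from scratch: it
simulates the matched-expression world with the given seed, runs the full
dual-track pipeline (scores, saGEX, clustering, metrics, differential
expression) into `results/acceptance_run/`, and writes the JSON report to
the `--out` path.

## Library surface

```python
from sansara import (
    read_pair, simulate_matched_expression_pair,   # IO / simulation
    select_hvg, pool_neighbors, fit_phase_portrait, compute_scores,  # scoring
    log_normalize, build_sagex, sagex_log_normalize,                 # saGEX
    RunConfig,
)
from sansara.embed_cluster import scale_features, pca, snn_cluster, map2d
from sansara.metrics import trustworthiness, continuity, adjusted_rand
from sansara.diffexpr import rank_markers, overlap_report
from sansara.pipeline import run_all
```

Every stage is also a CLI subcommand
(`sansara simulate|score|sagex|embed|metrics|de|run-all`), each accepting
`--config cfg.yaml`, `--seed`, `--outdir`.

See `docs/methods.md` for the model, estimator, pooling assumptions,
simulator design and numerical conventions.
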