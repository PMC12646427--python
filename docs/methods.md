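# Methods

## The problem

Droplet scRNA-seq reads can be classified by whether any part of the cDNA
overlaps an intron: intron-containing molecules are unspliced pre-mRNA,
intron-free molecules mature mRNA. Two cell populations can match each other
in *total* expression of a gene yet hold very different proportions of the
two forms — e.g. a subset storing translationally repressed mature mRNA, or
one holding an unspliced reservoir poised for rapid maturation. Conventional
expression analysis is blind to this axis. `sansara` folds the
spliced/unspliced balance into the feature matrix itself, so the ordinary
clustering/embedding/marker machinery can see it.

## Model and score

Per gene, a two-compartment kinetic model: transcription at rate α produces
unspliced molecules, splicing at rate β converts them, degradation at rate γ
removes mature molecules:

    du/dt = α − β·u,   ds/dt = β·u − γ·s

At steady state u* = α/β and s* = α/γ, so across cells at their steady
states the phase portrait (s, u) lies on a line through the origin with
slope γ/β. The per-cell, per-gene **splicing score** is the residual from
that line,

    v(c, g) = u(c, g) − γ̂_g · s(c, g),

a velocity-style quantity: v > 0 means an unspliced excess (the cell holds
more pre-mRNA than the gene's balance predicts), v < 0 a spliced excess.

γ̂ is estimated by zero-intercept least squares of u on s, restricted to the
cells in the bottom and top `fit_quantile` (default 0.05) of s — the
standard steady-state-cells assumption. A gene is discarded
(`passed_qc=False`) when either the restricted slope or the unrestricted
all-cell slope is zero: such genes are too poorly detected on one of the two
layers to be scored. This deterministic estimator replaces probabilistic
velocity fits deliberately: it is exactly reproducible on one CPU, and the
`ScoreMatrix` interface does not care how the score was produced.

## saGEX construction

1. `log_normalize`: e(c,g) = log1p(count/total · 10⁴) on total
   (spliced+unspliced) counts; the standard library-size normalization.
2. Multiply: raw(c,g) = e(c,g) · v(c,g). Scores are max-abs scaled per gene
   by default (`scale_scores`) so genes with large absolute velocities do
   not dominate the product.
3. Sign-split: `g.s` = |raw| where raw < 0, `g.u` = raw where raw > 0. Per
   cell and gene at most one of the pair is non-zero, and
   g.s + g.u = |e·v| exactly (asserted in tests, not just documented).
4. Optionally (`renormalize_sagex`, default on) the saGEX matrix is
   log-normalized again, treating its values as pseudo-counts; cells with no
   splicing signal on any retained gene are dropped and recorded in
   provenance.

Downstream, saGEX flows through exactly the pipeline that conventional
expression does — z-scoring clipped at ±10, PCA (50 components, top 25
used), optional embedding-level batch-correction hook, SNN graph (k=20,
Jaccard weights pruned below 1/15), Leiden modularity clustering over a
resolution sweep, optional UMAP — with identical parameters on both tracks,
so every comparison is paired.

## Neighbor pooling and its assumption

Raw per-cell counts are usually too sparse to place a single cell on a phase
portrait, so u and s are smoothed by averaging over each cell's k nearest
neighbors (self included) in PCA space of log-normalized totals
(`knn_k`, default 30 — the convention of velocity tooling).

Pooling carries a real assumption: **cells nearby in total-expression space
share splicing state.** When splicing varies independently of total
expression — precisely the situation this package exists to detect, and the
situation the matched-expression simulator plants — expression neighborhoods
are uninformative about the splicing axis, and pooling averages the signal
away: each pooled cell's splice fraction converges to the neighborhood
mixture mean, leaving ~1/k of the per-cell signal plus neighbor-composition
noise. On the matched-pair fixture this is drastic (planted-label ARI drops
from 1.0 without pooling to ~0 at k=30). Analyses of such data should set
`knn_k=1`; with real data, where populations differ in expression too,
pooling behaves as intended.

**Gamma fitting pools separately and heavily** (`gamma_pool_k`, default
100). The slope is a global per-gene parameter, so there is no per-cell
signal to preserve; what matters is that the extreme quantiles of s are
selected by genuine library-size spread and not by Poisson noise, which
would attenuate the slope for weakly expressed genes. Poisson variance of
the pooled s is s*/k against a depth-driven spread of σ_d²·s*², giving the
requirement k ≫ 1/(σ_d²·s*) ≈ 10/s* at σ_d = 0.3 — hence ~100 for genes
with one UMI per cell. With k=100 on 5,000-cell simulations, 96–99% of
expressed genes recover γ/β within 10%; at k=30, noise-selected tails pull
that to ~90%.

## Synthetic data

`simulate_steady_state` draws Poisson counts at the ODE fixed point:
u ~ Poisson(d_c·α/β), s ~ Poisson(d_c·α/γ), with per-cell depth factors d_c
lognormal (σ=0.3, mean exactly 1) and optional independent per-entry
dropout. Default kinetics are log-uniform — α ∈ (0.5, 20), β ∈ (0.5, 2),
γ ∈ (0.2, 1) — putting steady-state totals in the 1–60 UMI range of highly
variable genes and slopes γ/β in (0.1, 2).

`simulate_matched_expression_pair` plants the package's target situation:
for a designated gene subset, population A gets spliced fraction
0.5 + shift/2 and population B 0.5 − shift/2, with α set so expected totals
are identical across populations (per-gene totals log-uniform in (2, 20));
the remaining genes share one kinetics set with spliced fractions
U(0.3, 0.7). Total expression is exchangeable between populations by
construction, so any separation a splicing-unaware analysis finds is noise.

What the generator does **not** emulate: transient induction/repression
dynamics (cells sit at fixed points; there is no latent time), cell-cycle
structure, doublets, ambient RNA, gene–gene correlation beyond depth, or
batch effects. A green test on this world therefore establishes that the
machinery separates splicing structure under Poisson sampling noise at
realistic depths — not that it tolerates every artifact of real droplet
data.

## Metrics

- **Silhouette**: per-cell s_i = (b_i − a_i)/max(a_i, b_i), Euclidean in the
  given embedding; reported as the macro average (cluster means averaged
  with equal weight) alongside the per-cell mean. Fewer than two clusters →
  missing; singleton-cluster cells get 0.
- **Trustworthiness / continuity**: T(k) penalizes points in a cell's k-NN
  of the low-dimensional map that are not among its high-space neighbors,
  weighted by how far down the high-space ranking they sit
  (T = 1 − 2/(nk(2n−3k−1)) Σ (r−k)); continuity is the same penalty with
  the spaces swapped (true neighbors the map lost), i.e.
  continuity(h,l,k) = trustworthiness(l,h,k). Rank ties break by cell index
  for determinism.
- **Jaccard cluster map**: |a∩b|/|a∪b| per cluster pair across labelings.
- **Adjusted Rand index**: pair-counting agreement, chance-corrected under
  the permutation model; 1.0 when both partitions are identical (including
  the degenerate all-one-cluster case).
- **Per-cluster agreement**: for each pair of reference clusters, the
  fraction of cell pairs whose co-membership relation survives in the other
  labeling; no-pair entries are vacuously 1.

All five match exhaustive O(n²) reference implementations exactly in the
test suite.

## Differential expression

Two-sided Wilcoxon rank-sum per feature: exact enumeration of all group
assignments when both groups have ≤ 10 cells (valid under ties, where
classical exact tables are not), tie-corrected normal approximation
otherwise. log2FC = log2((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1)) — the
pseudocount-1, expm1-mean convention of mainstream single-cell pipelines.
Benjamini–Hochberg adjustment across the tested features of each
comparison; standard prefilters (min.pct 0.1, |log2FC| ≥ 0.25) are config
keys and can be set to 0. "Expressing" means value > 0; for saGEX features
a zero means no net spliced/unspliced signal. The spliced-vs-unaware
overlap report maps `g.s`/`g.u` back to g and intersects the gene sets
passing log2FC > 1.5 and p_adj < 0.05 (the p filter is an assumption — the
reference analysis states only the fold-change threshold).

## Numerical choices

- PCA uses full SVD with a deterministic orientation (largest-magnitude
  loading of each component made positive).
- Resolution 0 returns one cluster by definition: the γ=0 modularity
  optimum is merge-closed, but community detection on a disconnected graph
  may not merge components on its own.
- Cluster ids are relabeled by decreasing size (ties by first occurrence).
- SNN edges with Jaccard weight < 1/15 are pruned; the graph may be
  disconnected, which is logged and clustered as-is.
- Zero-variance features scale to all-zero rather than NaN; standardized
  values clip at ±10.
- A gene whose normalized values are constant to floating-point precision
  (variance below (10⁻¹² · mean)²) is treated as zero-dispersion in HVG
  ranking.
- Dispersion z-scores use quantile bins over gene means, capped so each bin
  holds at least ~10 genes; tiny panels fall back to a single bin.

## Limitations

- The steady-state estimator cannot separate induction/repression dynamics
  from population differences; it assumes the sampled cells bracket the
  steady state. Transient biology needs a dynamical-model fitter behind the
  same `ScoreMatrix` interface.
- The score scale is estimator-dependent; saGEX magnitudes are comparable
  within a run, not across estimators.
- Batch correction is a hook; with `method="none"` multi-donor structure
  remains in the embedding.
- Metrics materialize dense rank matrices (O(n²) memory); fine to ~20k
  cells, not beyond.
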