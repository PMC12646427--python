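"""Scale -> PCA -> (batch hook) -> SNN graph -> community clustering -> 2-D map.

The identical operation sequence is run on conventional expression and on
saGEX features so that every downstream comparison is paired.  Defaults
follow the common single-cell pipeline: 50 PCs computed, top 25 used, kNN
k=20, shared-nearest-neighbor Jaccard weights pruned below 1/15, modularity
community detection over a resolution sweep.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "ClusterLabels",
    "scale_features",
    "pca",
    "batch_correct",
    "snn_graph",
    "snn_cluster",
    "map2d",
    "merge_clusters",
]

SNN_PRUNE = 1.0 / 15.0


@dataclass
class Embedding:
    """Low-dimensional coordinates with provenance."""

    coords: np.ndarray
    space: str  # 'pca' | 'corrected_pca' | 'map2d'
    provenance: dict = field(default_factory=dict)
    explained_variance_ratio: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite coordinates")
        if self.space == "map2d" and self.coords.shape[1] < 2:
            raise ValueError("map2d embedding must have >= 2 dimensions")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class ClusterLabels:
    """Integer cluster assignment (0..K-1, every value occupied) at one resolution."""

    labels: np.ndarray
    resolution: float
    n_clusters: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            # canonicalize to a dense 0..K-1 coding
            remap = {old: new for new, old in enumerate(uniq)}
            self.labels = np.array([remap[x] for x in self.labels])
        self.n_clusters = int(self.labels.max()) + 1 if self.labels.size else 0


def scale_features(x, clip: float = 10.0) -> np.ndarray:
    """Per-feature z-scoring (ddof=1), zero-variance features zeroed, clip at +/-clip."""
    dense = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    mean = dense.mean(axis=0)
    sd = dense.std(axis=0, ddof=1) if dense.shape[0] > 1 else np.zeros(dense.shape[1])
    out = dense - mean
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return np.clip(out, -clip, clip)


def pca(scaled: np.ndarray, n_pcs: int = 50, random_state: int = 0) -> Embedding:
    """Full-SVD PCA with a deterministic sign convention.

    Each component is oriented so its largest-magnitude loading is positive,
    making coordinates stable across runs and platforms.
    """
    scaled = np.asarray(scaled, dtype=float)
    max_pcs = min(scaled.shape[0], scaled.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} reduced to {max_pcs} (matrix is {scaled.shape})")
        n_pcs = max_pcs
    model = PCA(n_components=n_pcs, svd_solver="full", random_state=random_state)
    coords = model.fit_transform(scaled)
    comps = model.components_
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1.0
            coords[:, k] *= -1.0
    return Embedding(
        coords=coords,
        space="pca",
        provenance={"n_pcs": n_pcs, "components": comps, "mean": model.mean_},
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def batch_correct(
    embedding: Embedding,
    batch_labels=None,
    method_hook: Optional[Callable] = None,
    n_keep: int = 25,
) -> Embedding:
    """Optional embedding-level batch correction, then truncation to ``n_keep`` PCs.

    ``method_hook(coords, batch_labels) -> corrected_coords`` lets an external
    method (e.g. Harmony) stand in; with no hook the embedding passes through
    unchanged apart from truncation.  The hook must preserve the matrix shape.
    """
    coords = embedding.coords
    space = "corrected_pca"
    if method_hook is not None:
        if batch_labels is None:
            raise ValueError("batch_labels required when a correction hook is given")
        if len(batch_labels) != coords.shape[0]:
            raise ValueError(
                f"batch label count {len(batch_labels)} does not match cells {coords.shape[0]}"
            )
        corrected = np.asarray(method_hook(coords, np.asarray(batch_labels)))
        if corrected.shape != coords.shape:
            raise ValueError(
                f"correction hook returned shape {corrected.shape}, expected {coords.shape}"
            )
        coords = corrected
    n_keep = min(n_keep, coords.shape[1])
    return Embedding(
        coords=coords[:, :n_keep].copy(),
        space=space,
        provenance={**embedding.provenance, "n_keep": n_keep,
                    "corrected": method_hook is not None},
    )


def snn_graph(coords: np.ndarray, k: int = 20, prune: float = SNN_PRUNE):
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighborhood is its k nearest cells (self included).  The
    edge weight between i and j is |N_i & N_j| / |N_i | N_j|; weights below
    ``prune`` are dropped.  Returns an igraph Graph.
    """
    import igraph

    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    idx = nn.kneighbors(coords, return_distance=False)
    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    shared = (adj @ adj.T).tocoo()  # |N_i & N_j|
    mask = shared.row < shared.col
    r, c, inter = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = inter / (2 * k - inter)
    keep = jac >= prune
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    if len(g.connected_components()) > 1:
        logger.info("SNN graph has %d connected components", len(g.connected_components()))
    return g


def snn_cluster(
    embedding: Embedding,
    k: int = 20,
    resolutions: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5),
    seed: int = 0,
    prune: float = SNN_PRUNE,
) -> list:
    """Leiden modularity clustering on the SNN graph over a resolution sweep.

    Resolution 0 is by definition the degenerate optimum where all cells form
    one community.  Cluster ids are relabeled by decreasing size so that the
    labeling is deterministic given the seed.
    """
    import leidenalg

    for r in resolutions:
        if r < 0:
            raise ValueError(f"negative resolution {r}")
    graph = snn_graph(embedding.coords, k=k, prune=prune)
    out = []
    for res in resolutions:
        if res == 0:
            labels = np.zeros(embedding.n_cells, dtype=int)
        else:
            part = leidenalg.find_partition(
                graph,
                leidenalg.RBConfigurationVertexPartition,
                weights="weight",
                resolution_parameter=res,
                seed=seed,
                n_iterations=-1,
            )
            labels = np.asarray(part.membership)
            labels = _relabel_by_size(labels)
        out.append(ClusterLabels(labels=labels, resolution=float(res)))
    return out


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(labels, return_counts=True)
    # sort by size desc, ties by first occurrence for determinism
    first = np.array([np.argmax(labels == u) for u in uniq])
    order = np.lexsort((first, -counts))
    remap = {int(uniq[o]): rank for rank, o in enumerate(order)}
    return np.array([remap[int(x)] for x in labels])


def map2d(embedding: Embedding, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1) -> Embedding:
    """2-D UMAP of the (corrected) PCA space; deterministic for a fixed seed."""
    try:
        import umap
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "umap-learn is not installed; 2-D maps are unavailable "
            "(the rest of the pipeline does not require them)"
        ) from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
        )
        coords = reducer.fit_transform(embedding.coords)
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        space="map2d",
        provenance={"source": embedding.space, "seed": seed, "n_neighbors": n_neighbors},
    )


def merge_clusters(labels: ClusterLabels, groups: dict) -> ClusterLabels:
    """Merge clusters that share an (externally assigned) annotation.

    ``groups`` maps old cluster id -> group key; clusters absent from the
    mapping keep their own identity.  Resulting ids are re-coded 0..K-1.
    """
    merged = np.array([
        hash(("g", groups[x])) if x in groups else hash(("c", x))
        for x in labels.labels
    ])
    return ClusterLabels(labels=_canonical_codes(merged), resolution=labels.resolution)


def _canonical_codes(arr: np.ndarray) -> np.ndarray:
    codes = {}
    out = np.empty(len(arr), dtype=int)
    for i, x in enumerate(arr):
        if x not in codes:
            codes[x] = len(codes)
        out[i] = codes[x]
    return out
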