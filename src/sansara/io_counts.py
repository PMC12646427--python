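"""Paired spliced/unspliced count matrices and saGEX matrices, on disk and in memory.

Disk layout follows the velocyto / CellRanger convention: MatrixMarket
coordinate matrices with **genes as rows and cells as columns**, plus
``features.tsv`` / ``barcodes.tsv`` sidecars.  In memory everything is
cells x genes (scipy CSR), i.e. transposed relative to disk.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "SplicedUnsplicedMatrix",
    "SaGEXMatrix",
    "read_pair",
    "write_pair",
    "splice_fraction_summary",
    "write_sagex",
    "read_sagex",
]


def _as_csr(x) -> sp.csr_matrix:
    if sp.issparse(x):
        return x.tocsr()
    return sp.csr_matrix(np.asarray(x))


@dataclass
class SplicedUnsplicedMatrix:
    """Two non-negative integer count layers over one cells x genes grid.

    ``spliced`` counts molecules whose reads never touch an intron;
    ``unspliced`` counts molecules with at least some intronic sequence.
    Both layers share the same barcode (row) and gene (column) order.
    """

    spliced: sp.csr_matrix
    unspliced: sp.csr_matrix
    gene_ids: list
    barcodes: list
    gene_names: Optional[list] = None
    gene_flags: Optional[list] = None  # free-text per-gene flag (e.g. "designated")
    batch: Optional[np.ndarray] = None  # per-cell batch label

    def __post_init__(self):
        self.spliced = _as_csr(self.spliced)
        self.unspliced = _as_csr(self.unspliced)
        self.gene_ids = list(self.gene_ids)
        self.barcodes = list(self.barcodes)
        if self.gene_names is None:
            self.gene_names = list(self.gene_ids)
        self.validate()

    # -- properties ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    def totals(self) -> sp.csr_matrix:
        """Spliced + unspliced counts (the conventional 'GEX' counts)."""
        return (self.spliced + self.unspliced).tocsr()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError(
                f"layer shape mismatch: spliced {self.spliced.shape} vs "
                f"unspliced {self.unspliced.shape}"
            )
        n, g = self.spliced.shape
        if len(self.barcodes) != n:
            raise ValueError(f"{len(self.barcodes)} barcodes for {n} matrix rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {g} matrix columns")
        for name, layer in (("spliced", self.spliced), ("unspliced", self.unspliced)):
            if layer.nnz and layer.data.min() < 0:
                raise ValueError(f"negative entries in {name} layer")
            if layer.nnz and np.any(layer.data != np.round(layer.data)):
                raise ValueError(f"non-integer entries in {name} layer")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene_ids: {sorted(dup)[:5]}")
        dup = _duplicates(self.barcodes)
        if dup:
            raise ValueError(f"duplicate barcodes: {sorted(dup)[:5]}")
        if self.batch is not None and len(self.batch) != n:
            raise ValueError("batch labels length does not match cell count")

    def subset_genes(self, gene_ids: Sequence) -> "SplicedUnsplicedMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return SplicedUnsplicedMatrix(
            spliced=self.spliced[:, idx],
            unspliced=self.unspliced[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            barcodes=self.barcodes,
            gene_names=[self.gene_names[i] for i in idx],
            gene_flags=None if self.gene_flags is None else [self.gene_flags[i] for i in idx],
            batch=self.batch,
        )

    def to_anndata(self):
        """Convenience export to an AnnData with 'spliced'/'unspliced' layers."""
        import anndata

        ad = anndata.AnnData(
            X=self.totals(),
            obs=pd.DataFrame(index=self.barcodes),
            var=pd.DataFrame({"gene_name": self.gene_names}, index=self.gene_ids),
        )
        ad.layers["spliced"] = self.spliced.copy()
        ad.layers["unspliced"] = self.unspliced.copy()
        if self.batch is not None:
            ad.obs["batch"] = np.asarray(self.batch)
        return ad


_FEATURE_SUFFIX = re.compile(r"^(?P<gene>.+)\.(?P<kind>[su])$")


@dataclass
class SaGEXMatrix:
    """Splicing-adjusted expression: two non-negative features per gene.

    For each retained gene g the features are ``g.s`` (spliced form) and
    ``g.u`` (unspliced form).  In any one cell at most one of the pair is
    non-zero: the splicing score that produced the value has a single sign.
    """

    values: sp.csr_matrix
    feature_names: list
    barcodes: list
    gene_ids: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = _as_csr(self.values)
        self.feature_names = list(self.feature_names)
        self.barcodes = list(self.barcodes)
        if not self.gene_ids:
            self.gene_ids = self._genes_from_features()
        self.validate()

    def _genes_from_features(self) -> list:
        genes = []
        for f in self.feature_names[::2]:
            m = _FEATURE_SUFFIX.match(f)
            genes.append(m.group("gene") if m else f)
        return genes

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        n, f = self.values.shape
        if len(self.barcodes) != n:
            raise ValueError(f"{len(self.barcodes)} barcodes for {n} rows")
        if len(self.feature_names) != f:
            raise ValueError(f"{len(self.feature_names)} feature names for {f} columns")
        if f != 2 * len(self.gene_ids):
            raise ValueError(
                f"feature count {f} is not 2 x gene count {len(self.gene_ids)}"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative saGEX values")
        # mutual exclusivity: per cell/gene at most one of (g.s, g.u) non-zero
        dense_prod = self.spliced_part().multiply(self.unspliced_part())
        if dense_prod.nnz and np.any(dense_prod.data != 0):
            raise ValueError("spliced and unspliced features both non-zero for some cell/gene")

    def spliced_part(self) -> sp.csr_matrix:
        """Cells x genes matrix of the '.s' features."""
        return self.values[:, 0::2].tocsr()

    def unspliced_part(self) -> sp.csr_matrix:
        """Cells x genes matrix of the '.u' features."""
        return self.values[:, 1::2].tocsr()


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


# ---------------------------------------------------------------------------
# paired count matrices
# ---------------------------------------------------------------------------

def _read_features(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty features file: {path}") from exc
    if df.shape[0] == 0:
        raise ValueError(f"empty features file: {path}")
    return df


def read_pair(directory) -> SplicedUnsplicedMatrix:
    """Read spliced.mtx / unspliced.mtx / features.tsv / barcodes.tsv.

    On disk matrices are genes x cells; the returned object is cells x genes.
    """
    d = Path(directory)
    mats = {}
    for layer in ("spliced", "unspliced"):
        p = d / f"{layer}.mtx"
        if not p.exists():
            raise FileNotFoundError(f"missing matrix file: {p}")
        m = scipy.io.mmread(p)
        if not np.issubdtype(np.asarray(m.data).dtype, np.integer):
            if np.any(m.data != np.round(m.data)):
                raise ValueError(f"non-integer entries in {p}")
        mats[layer] = sp.csr_matrix(m.T.astype(np.int64))  # -> cells x genes

    feats = _read_features(d / "features.tsv")
    bc_path = d / "barcodes.tsv"
    if not bc_path.exists():
        raise FileNotFoundError(f"missing sidecar file: {bc_path}")
    barcodes = [ln.strip() for ln in bc_path.read_text().splitlines() if ln.strip()]
    if not barcodes:
        raise ValueError(f"empty barcodes file: {bc_path}")

    if mats["spliced"].shape != mats["unspliced"].shape:
        raise ValueError(
            f"shape mismatch between layers in {d}: spliced (genes x cells) "
            f"{mats['spliced'].T.shape} vs unspliced {mats['unspliced'].T.shape}"
        )
    n, g = mats["spliced"].shape
    if len(feats) != g:
        raise ValueError(f"features.tsv lists {len(feats)} genes but matrices have {g}")
    if len(barcodes) != n:
        raise ValueError(f"barcodes.tsv lists {len(barcodes)} cells but matrices have {n}")

    gene_ids = feats[0].tolist()
    gene_names = feats[1].tolist() if feats.shape[1] > 1 else None
    gene_flags = feats[2].tolist() if feats.shape[1] > 2 else None

    batch = None
    batch_path = d / "batch.tsv"
    if batch_path.exists():
        bdf = pd.read_csv(batch_path, sep="\t", header=None, dtype=str)
        batch = bdf.set_index(0).loc[barcodes, 1].to_numpy()

    return SplicedUnsplicedMatrix(
        spliced=mats["spliced"],
        unspliced=mats["unspliced"],
        gene_ids=gene_ids,
        barcodes=barcodes,
        gene_names=gene_names,
        gene_flags=gene_flags,
        batch=batch,
    )


def write_pair(m: SplicedUnsplicedMatrix, directory) -> None:
    """Write the velocyto-style triplet (genes x cells on disk)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for layer, mat in (("spliced", m.spliced), ("unspliced", m.unspliced)):
        scipy.io.mmwrite(
            str(d / f"{layer}.mtx"), sp.coo_matrix(mat.T.astype(np.int64)), field="integer"
        )
    flags = m.gene_flags if m.gene_flags is not None else [""] * m.n_genes
    feats = pd.DataFrame({"id": m.gene_ids, "name": m.gene_names, "flag": flags})
    feats.to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    (d / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))
    if m.batch is not None:
        pd.DataFrame({"bc": m.barcodes, "batch": m.batch}).to_csv(
            d / "batch.tsv", sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# splice fraction diagnostics
# ---------------------------------------------------------------------------

def splice_fraction_summary(m: SplicedUnsplicedMatrix, labels=None) -> dict:
    """Spliced / (spliced + unspliced) fractions per cell, per gene and per group.

    Entries with zero total counts are reported as missing (NaN), never as 0.
    Returns a dict of DataFrames with keys 'per_cell', 'per_gene' and, when
    ``labels`` is given, 'per_group'.
    """
    if labels is not None and len(labels) != m.n_cells:
        raise ValueError(
            f"labels length {len(labels)} does not match cell count {m.n_cells}"
        )
    s_cell = np.asarray(m.spliced.sum(axis=1)).ravel().astype(float)
    u_cell = np.asarray(m.unspliced.sum(axis=1)).ravel().astype(float)
    tot = s_cell + u_cell
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_cell = np.where(tot > 0, s_cell / tot, np.nan)
    per_cell = pd.DataFrame(
        {"barcode": m.barcodes, "spliced": s_cell, "unspliced": u_cell,
         "fraction_spliced": frac_cell}
    )

    s_gene = np.asarray(m.spliced.sum(axis=0)).ravel().astype(float)
    u_gene = np.asarray(m.unspliced.sum(axis=0)).ravel().astype(float)
    tot_g = s_gene + u_gene
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_gene = np.where(tot_g > 0, s_gene / tot_g, np.nan)
    per_gene = pd.DataFrame(
        {"gene_id": m.gene_ids, "spliced": s_gene, "unspliced": u_gene,
         "fraction_spliced": frac_gene}
    )

    out = {"per_cell": per_cell, "per_gene": per_gene}
    if labels is not None:
        labels = np.asarray(labels)
        rows = []
        for lab in pd.unique(labels):
            mask = labels == lab
            s = float(m.spliced[mask].sum())
            u = float(m.unspliced[mask].sum())
            rows.append(
                {"group": lab, "spliced": s, "unspliced": u,
                 "fraction_spliced": s / (s + u) if s + u > 0 else np.nan}
            )
        out["per_group"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# saGEX IO
# ---------------------------------------------------------------------------

def write_sagex(m: SaGEXMatrix, directory) -> None:
    """Write sagex.mtx (features x cells, real general) + sidecars + provenance."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "sagex.mtx"), sp.coo_matrix(m.values.T), field="real")
    kinds = [f.rsplit(".", 1)[-1] for f in m.feature_names]
    genes = [f.rsplit(".", 1)[0] for f in m.feature_names]
    pd.DataFrame({"feature": m.feature_names, "gene": genes, "kind": kinds}).to_csv(
        d / "sagex_features.tsv", sep="\t", header=False, index=False
    )
    (d / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))
    with open(d / "provenance.json", "w") as fh:
        json.dump(m.provenance, fh, indent=1, default=str)


def read_sagex(directory) -> SaGEXMatrix:
    d = Path(directory)
    p = d / "sagex.mtx"
    if not p.exists():
        raise FileNotFoundError(f"missing matrix file: {p}")
    try:
        vals = sp.csr_matrix(scipy.io.mmread(p).T)
    except ValueError as exc:
        raise ValueError(f"corrupt MatrixMarket header in {p}: {exc}") from exc
    feats = _read_features(d / "sagex_features.tsv")
    barcodes = [ln.strip() for ln in (d / "barcodes.tsv").read_text().splitlines() if ln.strip()]
    prov = {}
    if (d / "provenance.json").exists():
        prov = json.loads((d / "provenance.json").read_text())
    return SaGEXMatrix(
        values=vals,
        feature_names=feats[0].tolist(),
        barcodes=barcodes,
        provenance=prov,
    )
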