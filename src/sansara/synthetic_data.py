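"""Simulate spliced/unspliced UMI count matrices from two-compartment RNA kinetics.

The model: each gene g transcribes pre-mRNA at rate alpha, splices it at rate
beta and degrades mature mRNA at rate gamma.  At the fixed point of

    du/dt = alpha - beta * u
    ds/dt = beta * u - gamma * s

the expected abundances are u* = alpha/beta and s* = alpha/gamma.  Cells are
drawn at this steady state: counts are Poisson around depth-scaled means,
optionally thinned by an independent per-entry dropout.  This is deliberately
a stable-population world — no induction/repression transients, no cell
cycle — because the analysis the counts feed targets stable cell subsets
that differ in splicing state rather than in trajectory position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .io_counts import SplicedUnsplicedMatrix, write_pair

__all__ = [
    "GeneKinetics",
    "PopulationSpec",
    "SimulationConfig",
    "default_kinetics",
    "simulate_steady_state",
    "simulate_matched_expression_pair",
    "write_fixture",
]

#: default per-cell library-size spread (lognormal sigma); mean multiplier is 1
DEPTH_SIGMA = 0.3


@dataclass(frozen=True)
class GeneKinetics:
    """Transcription (alpha), splicing (beta) and degradation (gamma) rates.

    Units: alpha in molecules per unit time; beta and gamma in 1/unit time.
    Steady-state means are u* = alpha/beta (unspliced), s* = alpha/gamma
    (spliced); the phase-portrait slope of u on s is gamma/beta.
    """

    alpha: float
    beta: float
    gamma: float

    @property
    def mean_unspliced(self) -> float:
        return self.alpha / self.beta

    @property
    def mean_spliced(self) -> float:
        return self.alpha / self.gamma

    @property
    def slope(self) -> float:
        """Steady-state ratio gamma/beta: slope of unspliced on spliced."""
        return self.gamma / self.beta


@dataclass
class PopulationSpec:
    """One planted cell population: shared gene list, its own kinetics."""

    n_cells: int
    kinetics: Sequence[GeneKinetics]
    label: str
    depth_sigma: float = DEPTH_SIGMA

    def validate(self, gene_ids: Sequence[str]) -> None:
        if self.n_cells < 1:
            raise ValueError(f"population {self.label!r}: n_cells must be >= 1")
        if len(self.kinetics) != len(gene_ids):
            raise ValueError(
                f"population {self.label!r}: {len(self.kinetics)} kinetics "
                f"entries for {len(gene_ids)} genes"
            )
        for gid, kin in zip(gene_ids, self.kinetics):
            for rate in ("alpha", "beta", "gamma"):
                val = getattr(kin, rate)
                if not val > 0:
                    raise ValueError(
                        f"gene {gid} in population {self.label!r}: "
                        f"rate {rate}={val} must be strictly positive"
                    )


@dataclass
class SimulationConfig:
    populations: list
    seed: int
    dropout_rate: float = 0.0
    gene_ids: Optional[list] = None
    gene_flags: Optional[list] = None

    def validate(self) -> None:
        if not self.populations:
            raise ValueError("at least one population required")
        n_genes = len(self.populations[0].kinetics)
        if n_genes < 1:
            raise ValueError("at least one gene required")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate {self.dropout_rate} outside [0, 1]")
        gene_ids = self.gene_ids or _gene_names(n_genes)
        for pop in self.populations:
            pop.validate(gene_ids)


def _gene_names(n: int) -> list:
    return [f"G{i + 1:04d}" for i in range(n)]


def default_kinetics(
    n_genes: int,
    rng: np.random.Generator,
    alpha_range=(0.5, 20.0),
    beta_range=(0.5, 2.0),
    gamma_range=(0.2, 1.0),
) -> list:
    """Log-uniform random kinetics spanning lowly to moderately expressed genes.

    The defaults put steady-state totals roughly in the 1-60 UMI range —
    the regime of highly variable genes in droplet scRNA-seq — with
    phase-portrait slopes gamma/beta between 0.1 and 2.
    """
    def logu(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    alphas = logu(*alpha_range, n_genes)
    betas = logu(*beta_range, n_genes)
    gammas = logu(*gamma_range, n_genes)
    return [GeneKinetics(a, b, g) for a, b, g in zip(alphas, betas, gammas)]


def simulate_steady_state(config: SimulationConfig):
    """Draw Poisson counts at the kinetic fixed point for every population.

    Per cell c with depth factor d_c (lognormal, mean 1) and gene g:
    unspliced ~ Poisson(d_c * alpha/beta), spliced ~ Poisson(d_c * alpha/gamma),
    then each entry is independently zeroed with probability
    ``config.dropout_rate``.

    Returns (SplicedUnsplicedMatrix, labels) where labels is an array of the
    population label of each cell.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = len(config.populations[0].kinetics)
    gene_ids = config.gene_ids or _gene_names(n_genes)

    u_blocks, s_blocks, labels = [], [], []
    for pop in config.populations:
        mean_u = np.array([k.mean_unspliced for k in pop.kinetics])
        mean_s = np.array([k.mean_spliced for k in pop.kinetics])
        # lognormal with mean exactly 1: mu = -sigma^2/2
        sig = pop.depth_sigma
        depth = rng.lognormal(-0.5 * sig**2, sig, size=pop.n_cells) if sig > 0 else np.ones(pop.n_cells)
        u = rng.poisson(np.outer(depth, mean_u))
        s = rng.poisson(np.outer(depth, mean_s))
        if config.dropout_rate > 0:
            u = np.where(rng.random(u.shape) < config.dropout_rate, 0, u)
            s = np.where(rng.random(s.shape) < config.dropout_rate, 0, s)
        u_blocks.append(u)
        s_blocks.append(s)
        labels.extend([pop.label] * pop.n_cells)

    u_all = np.vstack(u_blocks)
    s_all = np.vstack(s_blocks)
    n_cells = u_all.shape[0]
    barcodes = [f"cell{i + 1:06d}" for i in range(n_cells)]
    mat = SplicedUnsplicedMatrix(
        spliced=sp.csr_matrix(s_all),
        unspliced=sp.csr_matrix(u_all),
        gene_ids=gene_ids,
        barcodes=barcodes,
        gene_flags=config.gene_flags,
    )
    return mat, np.asarray(labels)


def simulate_matched_expression_pair(
    n_cells_per_pop: int,
    n_genes: int,
    splice_shift: float,
    seed: int,
    n_designated: Optional[int] = None,
    total_range=(2.0, 20.0),
    background_fraction_range=(0.3, 0.7),
    depth_sigma: float = DEPTH_SIGMA,
    dropout_rate: float = 0.0,
):
    """Two populations with identical expected totals but shifted splice state.

    For a designated subset of genes, population A is given spliced fraction
    ``0.5 + splice_shift/2`` and population B ``0.5 - splice_shift/2``, with
    alpha chosen so the expected total (spliced + unspliced) count per gene is
    identical across populations.  The remaining genes share one kinetics set.
    A splicing-unaware analysis therefore sees two exchangeable populations;
    only the splice composition separates them.

    Returns (SplicedUnsplicedMatrix, labels); designated genes are flagged
    "designated" in ``gene_flags``.
    """
    if not 0.0 < splice_shift < 1.0:
        raise ValueError(f"splice_shift {splice_shift} outside the open interval (0, 1)")
    if n_designated is None:
        n_designated = n_genes // 4
    if n_designated > n_genes:
        raise ValueError("n_designated exceeds n_genes")

    rng = np.random.default_rng(seed)
    log_lo, log_hi = np.log(total_range[0]), np.log(total_range[1])
    totals = np.exp(rng.uniform(log_lo, log_hi, n_genes))
    frac_bg = rng.uniform(*background_fraction_range, n_genes)

    frac_a = frac_bg.copy()
    frac_b = frac_bg.copy()
    designated = np.zeros(n_genes, dtype=bool)
    designated[:n_designated] = True
    frac_a[designated] = 0.5 + splice_shift / 2.0
    frac_b[designated] = 0.5 - splice_shift / 2.0

    def kinetics_for(frac):
        # beta = 1; u* = (1-f)*T fixes alpha, s* = f*T fixes gamma
        out = []
        for T, f in zip(totals, frac):
            alpha = (1.0 - f) * T
            gamma = alpha / (f * T)
            out.append(GeneKinetics(alpha=alpha, beta=1.0, gamma=gamma))
        return out

    pops = [
        PopulationSpec(n_cells_per_pop, kinetics_for(frac_a), "popA", depth_sigma),
        PopulationSpec(n_cells_per_pop, kinetics_for(frac_b), "popB", depth_sigma),
    ]
    flags = ["designated" if d else "" for d in designated]
    config = SimulationConfig(
        populations=pops,
        seed=seed,
        dropout_rate=dropout_rate,
        gene_flags=flags,
    )
    return simulate_steady_state(config)


def write_fixture(matrix: SplicedUnsplicedMatrix, labels, directory) -> None:
    """Write the velocyto-style triplet plus labels.tsv (barcode TAB label)."""
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("refusing to write an empty matrix fixture")
    if len(labels) != matrix.n_cells:
        raise ValueError(
            f"labels length {len(labels)} does not match cell count {matrix.n_cells}"
        )
    d = Path(directory)
    try:
        write_pair(matrix, d)
        with open(d / "labels.tsv", "w") as fh:
            for bc, lab in zip(matrix.barcodes, labels):
                fh.write(f"{bc}\t{lab}\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture under {d}: {exc}") from exc


def read_labels(directory) -> np.ndarray:
    """Read labels.tsv written by :func:`write_fixture` (barcode order preserved)."""
    path = Path(directory) / "labels.tsv"
    labels = []
    for ln in path.read_text().splitlines():
        if ln.strip():
            labels.append(ln.split("\t")[1])
    return np.asarray(labels)
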