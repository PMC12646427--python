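"""Run configuration: one flat record of every tunable, serialized with outputs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline knobs.  Defaults follow the standard single-cell pipeline."""

    seed: int = 0

    # simulation (used when no input directory is given)
    n_cells_per_pop: int = 500
    n_genes: int = 200
    n_designated: int = 50
    splice_shift: float = 0.6
    dropout_rate: float = 0.0
    depth_sigma: float = 0.3

    # scoring
    n_top_hvg: int = 2000
    knn_k: int = 30
    gamma_pool_k: int = 100
    fit_quantile: float = 0.05
    scale_scores: bool = True
    exclude_patterns: tuple = (r"^TR[ABGD][VDJC]",)

    # saGEX
    scale_factor: float = 1e4
    renormalize_sagex: bool = True

    # embedding / clustering
    n_pcs: int = 50
    n_pcs_used: int = 25
    cluster_k: int = 20
    snn_prune: float = 1.0 / 15.0
    resolutions: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)
    batch_method: str = "none"
    make_map: bool = True

    # metrics
    metric_ks: tuple = (5, 15, 30)

    # differential expression
    de_resolution: float = 1.0
    de_min_pct: float = 0.1
    de_min_log2fc: float = 0.25
    de_lfc_threshold: float = 1.5
    de_padj_threshold: float = 0.05

    # paths
    input_dir: Optional[str] = None

    def validate(self) -> None:
        if any(r < 0 for r in self.resolutions):
            raise ValueError(f"negative resolution in {self.resolutions}")
        if not 0 < self.fit_quantile <= 0.5:
            raise ValueError(f"fit_quantile {self.fit_quantile} outside (0, 0.5]")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError(f"dropout_rate {self.dropout_rate} outside [0, 1]")
        if self.n_pcs_used > self.n_pcs:
            raise ValueError("n_pcs_used cannot exceed n_pcs")
        for name in ("n_cells_per_pop", "n_genes", "n_top_hvg", "knn_k", "cluster_k", "n_pcs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("resolutions", "metric_ks", "exclude_patterns"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("resolutions", "metric_ks", "exclude_patterns"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def write_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
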