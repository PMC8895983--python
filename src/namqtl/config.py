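"""Pipeline configuration: stage parameters, paths, and run mode."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # run mode: end-to-end on provided files, or self-contained synthetic run
    mode: str = "synthetic-validation"       # or "real-data"

    # input paths (real-data mode; optional in synthetic mode)
    map_path: str | None = None
    genotypes_path: str | None = None
    variants_path: str | None = None
    plots_path: str | None = None
    blues_path: str | None = None
    annotations_path: str | None = None
    apriori_path: str | None = None

    # stage parameters
    n_perm: int = 1000
    alpha: float = 0.05
    interval_alpha: float = 0.01
    n_iter: int = 100
    subsample: float = 0.8
    rmip_report: int = 5
    window_bp: int = 250_000
    r_threshold: float = 0.8
    fdr: float = 0.05
    n_trees: int = 1000
    test_fraction: float = 0.3
    n_rf_seeds: int = 30
    # |DFFITS| cutoff for outlier flagging. The augmented design has high
    # per-plot leverage (few replicates per line), so the classical
    # 2*sqrt(p/n) rule flags far too much; an absolute cutoff of 3 keeps
    # flagging conservative (<1% of clean Gaussian data). Set to None to
    # fall back to 2*sqrt(p/n).
    dffits_threshold: float | None = 3.0
    seed: int = 1

    # synthetic-validation scale
    n_chrom: int = 3
    chrom_length_cM: float = 100.0
    step_cM: float = 1.0
    n_ril: int = 40
    variant_density_per_Mb: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic-validation", "real-data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("alpha", "interval_alpha", "subsample", "fdr",
                     "test_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_perm", "n_iter", "window_bp", "n_trees", "n_ril",
                     "n_chrom", "n_rf_seeds", "rmip_report"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialization --------------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
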