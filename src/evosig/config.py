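"""Declarative pipeline configuration (YAML).

Every threshold the analysis uses is surfaced here with the study's value as
the default: gap flank 10, impact cutoff 0.05, FDR 0.05, site posterior 0.95,
fuzzy one-to-one fraction 0.75.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PanelConfig:
    species: list[str] = field(default_factory=list)  # empty = generated names
    focal: str = "sp01"
    outgroup: str = "sp17"

    def __post_init__(self):
        if self.focal == self.outgroup:
            raise ValueError("focal and outgroup must differ")


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_orthogroups: int = 20
    n_species: int = 17
    n_codons: int = 150
    mean_depth: float = 0.5
    kappa: float = 2.0
    omega0: float = 0.2
    p0: float = 0.75
    p1: float = 0.15
    n_selected: int = 5  # orthogroups simulated with omega2 on the focal branch
    omega2: float = 8.0
    n_divergent: int = 5  # orthogroups with a rate-accelerated focal branch
    focal_rate_multiplier: float = 3.0
    n_unique: int = 5  # orthogroups with planted unique substitutions
    n_planted_sites: int = 4
    gap_rate: float = 0.0
    gap_flank_clearance: int = 10


@dataclass
class Thresholds:
    flank: int = 10
    sift_cutoff: float = 0.05
    fdr: float = 0.05
    posterior: float = 0.95
    fuzziness: float = 0.75
    max_copies: int = 3
    divergence_mode: str = "max"
    divergence_ratio: float = 1.0
    divergence_z: float = 2.0

    def __post_init__(self):
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        for name in ("sift_cutoff", "fdr", "posterior", "fuzziness"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.divergence_mode not in ("max", "zscore"):
            raise ValueError("divergence_mode must be 'max' or 'zscore'")


@dataclass
class PipelineConfig:
    workdir: str = "evosig_run"
    panel: PanelConfig = field(default_factory=PanelConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    fit_starts: int = 3
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "orthogroups", "signatures", "call"]
    )
    resume: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("panel", PanelConfig),
            ("simulate", SimulateConfig),
            ("thresholds", Thresholds),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
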