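"""Pipeline configuration with lossless YAML round-tripping.

Defaults mirror the analysis conventions the pipeline reproduces: a
0.20 mitochondrial-fraction QC cutoff, top-10 compartment markers for
the signatures, a 0.20 coexpression threshold for transition cells, and
top-100 driver lists.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import QCThresholds


@dataclass
class VelocityParams:
    extreme_quantile: float = 0.05
    smoothing_k: int = 30
    n_pcs: int = 30
    top_n_drivers: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.extreme_quantile <= 0.5:
            raise ValueError("extreme_quantile must lie in (0, 0.5]")


@dataclass
class SignatureParams:
    n_top_markers: int = 10
    coexpression_threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0 <= self.coexpression_threshold <= 0.25:
            raise ValueError("coexpression_threshold outside the attainable [0, 0.25]")


@dataclass
class RegulonParams:
    top_fraction: float = 0.05
    top_k_active: int = 30


@dataclass
class DriverRegulatorParams:
    min_driver_targets: int = 1
    start_tercile: float = 1 / 3   # fraction of the non-myogenic cluster, by s_n, used
    #                               as the "start of the trajectory" for driver ranking


@dataclass
class PipelinePaths:
    spliced_dir: str = ""
    unspliced_dir: str = ""
    metadata: str = ""
    regulons_gmt: str = ""
    lr_pairs: str = ""


@dataclass
class PipelineConfig:
    paths: PipelinePaths = field(default_factory=PipelinePaths)
    qc: QCThresholds = field(default_factory=QCThresholds)
    normalization: str = "median_log1p"
    velocity: VelocityParams = field(default_factory=VelocityParams)
    signatures: SignatureParams = field(default_factory=SignatureParams)
    regulons: RegulonParams = field(default_factory=RegulonParams)
    driver_regulators: DriverRegulatorParams = field(default_factory=DriverRegulatorParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        return cls(
            paths=PipelinePaths(**d.get("paths", {})),
            qc=QCThresholds(**d.get("qc", {})),
            normalization=d.get("normalization", "median_log1p"),
            velocity=VelocityParams(**d.get("velocity", {})),
            signatures=SignatureParams(**d.get("signatures", {})),
            regulons=RegulonParams(**d.get("regulons", {})),
            driver_regulators=DriverRegulatorParams(**d.get("driver_regulators", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def config_hash(self) -> str:
        """Short stable digest of the canonical config serialization."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
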