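"""Pipeline configuration: one object (or YAML block) per stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from armnet.clustering import DEFAULT_RESOLUTIONS
from armnet.qc import QcThresholds


@dataclass
class ClusteringParams:
    resolutions: tuple[float, ...] = DEFAULT_RESOLUTIONS
    backend: str = "leiden"
    n_pcs: int = 50
    n_neighbors: int = 15
    # microglia re-clustering: a single, higher resolution so that small
    # contaminant/doublet clusters separate from genuine subtypes
    microglia_resolution: float = 2.0
    microglia_n_pcs: int = 20


@dataclass
class PreprocessParams:
    target: float = 10000.0
    n_hvg: int = 2000
    n_hvg_microglia: int = 5000
    clip: float = 10.0
    # subtype composition varies across donors by design, so per-donor
    # standardization would erase the subtype signal in the re-clustering
    microglia_scale_scope: str = "global"


@dataclass
class DeParams:
    alpha: float = 0.05
    log2fc_threshold: float = 0.1
    min_cells: int = 3
    n_anova_genes: int = 477


@dataclass
class CsnParams:
    min_expression_rate: float = 0.05
    target_size: int = 50
    min_library: int = 200
    alpha_edge: float = 0.05
    h: float = 0.5
    neighborhood_frac: float = 0.1


@dataclass
class EnergyParams:
    alpha: float = 1.0
    n_perm: int = 999


@dataclass
class MixingParams:
    N: int = 100
    K: int = 100


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; stage seeds derive from ``seed``."""

    output_dir: str = "armnet_run"
    input_mtx_dir: str | None = None  # simulate when no input is given
    input_metadata: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    mixing: MixingParams = field(default_factory=MixingParams)
    de: DeParams = field(default_factory=DeParams)
    csn: CsnParams = field(default_factory=CsnParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    simulate_overrides: dict = field(default_factory=dict)
    microglia_type: str = "microglia"
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31, decoupled across stages."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("qc", QcThresholds),
            ("preprocess", PreprocessParams),
            ("clustering", ClusteringParams),
            ("mixing", MixingParams),
            ("de", DeParams),
            ("csn", CsnParams),
            ("energy", EnergyParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "clustering" in kwargs and isinstance(kwargs["clustering"], ClusteringParams):
            kwargs["clustering"].resolutions = tuple(kwargs["clustering"].resolutions)
        return cls(**kwargs)
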