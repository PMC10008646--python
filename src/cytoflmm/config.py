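"""Pipeline configuration and deterministic stage seeding."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import yaml

from .cluster import SomSpec
from .errors import ConfigError


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed and the stage name.

    Uses a CRC32 hash of the stage name so partial pipeline reruns reuse the
    same stream per stage regardless of stage order; result is < 2**31.
    """
    return (int(master_seed) ^ zlib.crc32(stage.encode("utf8"))) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline.

    Defaults follow the analysis the package implements: Daubechies-4 wavelet
    at decomposition level 4, 100 k-means restarts, three retained functional
    principal components per concentration level, 4 cubic B-splines, and
    Benjamini-Yekutieli control at q = 0.1.
    """

    wavelet: str = "db4"
    level: int = 4
    k_bins: int = 3
    kmeans_restarts: int = 100
    som: SomSpec = field(default_factory=SomSpec)
    n_fpc: int = 3
    e_var_threshold: float = 0.95
    n_basis: int = 4
    spline_degree: int = 3
    fdr_q: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if int(self.level) < 1:
            raise ConfigError(f"decomposition level must be >= 1, got {self.level}")
        if not (0.0 < float(self.fdr_q) < 1.0):
            raise ConfigError(f"FDR level q must be in (0, 1), got {self.fdr_q}")
        if not float(self.seed).is_integer():
            raise ConfigError("seed must be an integer")
        if int(self.n_fpc) < 1:
            raise ConfigError("n_fpc must be >= 1")
        if int(self.kmeans_restarts) < 1:
            raise ConfigError("kmeans_restarts must be >= 1")

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        som = raw.pop("som", None)
        cfg = cls(**raw)
        if som:
            cfg.som = SomSpec(**som)
        return cfg
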