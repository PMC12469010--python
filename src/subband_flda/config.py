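"""Pipeline configuration: one validated, serializable object per run.

A config round-trips through JSON/YAML unchanged, and its SHA-256 hash of the
canonical JSON form stamps every artifact a run writes, so output directories
are self-describing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError
from .shrinkage import ThresholdSpec


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with reproduction defaults.

    Defaults follow the source protocol: db4 wavelet, J = 6 decomposition
    levels, features at levels 3/4/6 under the "paper" band profile
    (gamma/beta/theta), soft universal-threshold shrinkage, subject-wise
    stratified 70/30 split, fixed seed 42, channel O2 excluded.
    """

    wavelet: str = "db4"
    J: int = 6
    levels: tuple[int, ...] = (3, 4, 6)
    band_profile: str = "paper"
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    split_fraction: float = 0.7
    seed: int = 42
    exclude_channels: tuple[str, ...] = ("O2",)
    ridge: float = 1e-6
    epoch_samples: int | None = None
    data_dir: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.levels = tuple(int(j) for j in self.levels)
        self.exclude_channels = tuple(self.exclude_channels)
        if isinstance(self.threshold, dict):
            self.threshold = ThresholdSpec.from_dict(self.threshold)
        if self.wavelet != "db4":
            raise ConfigError(f"only the db4 wavelet is supported, got {self.wavelet!r}")
        if self.J < 1:
            raise ConfigError(f"J must be >= 1, got {self.J}")
        bad = [j for j in self.levels if not 1 <= j <= self.J]
        if bad:
            raise ConfigError(f"levels {bad} outside 1..J={self.J}")
        if not self.levels:
            raise ConfigError("at least one feature level is required")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError(
                f"split_fraction must be in (0, 1), got {self.split_fraction}"
            )
        if self.band_profile not in ("paper", "dyadic"):
            raise ConfigError(f"unknown band_profile {self.band_profile!r}")
        if self.ridge < 0:
            raise ConfigError(f"ridge must be >= 0, got {self.ridge}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["levels"] = list(self.levels)
        d["exclude_channels"] = list(self.exclude_channels)
        d["threshold"] = self.threshold.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "threshold" in d and isinstance(d["threshold"], dict):
            d["threshold"] = ThresholdSpec.from_dict(d["threshold"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Load from a JSON or YAML file (by extension; YAML parses both)."""
        path = Path(path)
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(payload)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
        return path

    def hash(self) -> str:
        """SHA-256 of the canonical JSON form (paths excluded)."""
        d = self.to_dict()
        d.pop("data_dir", None)
        d.pop("out_dir", None)
        canon = json.dumps(d, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=int(seed))
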