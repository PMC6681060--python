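"""Run configuration: rule thresholds, grid geometry, evaluation defaults.

Serializes to/from YAML so a whole run is reproducible from one file; CLI
flags override config values and both end up hashed into the run manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .interactions import RuleSet


@dataclass
class RunConfig:
    rules: RuleSet = field(default_factory=RuleSet)
    edge: float = 0.1               # voxel edge, Angstrom
    neighborhood: float = 0.5       # Manhattan neighborhood radius, Angstrom
    rmsd_threshold: float = 2.0     # pose correctness cutoff, Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge <= 0 or self.neighborhood < 0 or self.rmsd_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rules" in d and isinstance(d["rules"], dict):
            d["rules"] = RuleSet.from_dict(d["rules"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
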