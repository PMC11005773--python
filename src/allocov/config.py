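"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    window_size: int = 100_000
    ploidy: int = 3
    baseline: str = "chromosome"  # "chromosome" | "genome"
    beta: str | float = "auto"  # "auto" or a fixed rate in [0, 0.5)
    min_windows: int = 5
    smooth_k: int = 5
    min_cluster_size: int = 3
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("window_size", "ploidy", "min_windows", "smooth_k",
                     "min_cluster_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline not in ("chromosome", "genome"):
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if self.beta != "auto":
            beta = float(self.beta)
            if not 0 <= beta < 0.5:
                raise ValueError("fixed beta must be in [0, 0.5)")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
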