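"""Analysis configuration: the handful of constants the pipeline conditions on."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Pipeline-wide constants.

    window_width
        Width of genomic analysis windows in bp (5 kb).
    gc_bin_width
        Width of GC-content bins as a fraction (5% intervals).
    boundary_flank
        Distance in bp examined on each side of a heterochromatin/euchromatin
        boundary (1 Mb at full genome scale).
    pseudocount
        Added to ChIP and input window coverage when forming ratios; 0 means
        zero-input windows become missing.
    top_k
        Number of top-ranked genes intersected in the overlap test (1,000).
    n_permutations
        Monte-Carlo permutations for the overlap null.
    rng_seed
        Seed recorded in every output header.
    """

    window_width: int = 5000
    gc_bin_width: float = 0.05
    boundary_flank: int = 1_000_000
    pseudocount: float = 0.0
    top_k: int = 1000
    n_permutations: int = 10_000
    rng_seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if not (0 < self.gc_bin_width <= 1):
            raise ValueError("gc_bin_width must be in (0, 1]")
        if self.boundary_flank <= 0:
            raise ValueError("boundary_flank must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        for name in ("top_k", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable digest of the configuration, for provenance headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load from a YAML mapping; keyword overrides beat file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)
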