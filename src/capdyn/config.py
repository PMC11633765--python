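"""Analysis configuration: every tunable default in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .types import ConfigurationError

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Pipeline parameters with the study's defaults.

    Units: FD threshold and head radius in mm, high-pass cutoff in Hz,
    smoothing FWHM in voxel units, selection threshold in z (SD) units,
    assignment threshold as a percentile of the reference correlation
    distribution.
    """

    # preprocessing
    fd_threshold_mm: float = 0.5
    head_radius_mm: float = 50.0
    highpass_hz: float = 0.01
    smooth_fwhm_vox: float | None = None
    global_signal: bool = True
    # frame selection
    select_mode: str = "z_threshold"  # or "top_fraction"
    select_z: float = 0.84
    top_fraction: float = 0.20
    # clustering
    k_range: tuple[int, int] = (2, 15)
    n_subsamples: int = 100
    subsample_frac: float = 0.8
    pac_bounds: tuple[float, float] = (0.1, 0.9)
    n_restarts: int = 20
    fixed_k: int | None = None  # skip the K scan when set
    # assignment
    assign_percentile: float = 5.0
    reassign_controls: bool = False
    # dynamics / stats
    gap_mode: str = "strict"  # or "collapse"
    alpha: float = 0.05
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.k_range = tuple(int(v) for v in self.k_range)
        self.pac_bounds = tuple(float(v) for v in self.pac_bounds)
        if self.select_mode not in ("z_threshold", "top_fraction"):
            raise ConfigurationError(f"unknown select_mode {self.select_mode!r}")
        if self.gap_mode not in ("strict", "collapse"):
            raise ConfigurationError(f"unknown gap_mode {self.gap_mode!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys in {path}: {', '.join(sorted(unknown))}"
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["pac_bounds"] = list(self.pac_bounds)
        return d

    def content_hash(self) -> str:
        """Stable hash of the configuration for the run manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
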