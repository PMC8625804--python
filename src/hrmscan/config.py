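"""Run configuration: one flat record of every tunable, loadable from YAML.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently running at defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .melt_core import SmoothingConfig


@dataclass
class RunConfig:
    """All analysis and simulation tunables for a CLI run."""

    # smoothing / domain detection
    window: int = 75
    polyorder: int = 3
    domain_threshold: float = 0.10
    peak_prominence: float = 0.10
    region_pad: float = 2.0
    min_domain_width: float = 0.5
    baseline_frac: float = 0.10
    # calling
    k: float = 2.0
    m: int = 10
    stratify_by_sex: bool = True
    combine_preparations: bool = True
    center: str = "median"
    # simulation
    seed: int = 0
    n_controls: int = 16
    n_variants: int = 8
    tm: float = 80.0
    slope: float = 1.0
    amplitude: float = 1000.0
    noise_sd: float = 5.0
    het_delta: float = -2.0
    hom_delta: float = -0.3
    grid_lo: float = 65.0
    grid_hi: float = 95.0
    grid_step: float = 0.04

    def __post_init__(self) -> None:
        # delegate the smoothing constraints to the type that owns them
        self.smoothing()
        if self.k <= 0:
            raise ConfigError("k must be positive")
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if not (0 < self.baseline_frac < 0.5):
            raise ConfigError("baseline_frac must be in (0, 0.5)")
        if self.center not in ("median", "mean"):
            raise ConfigError(f"center must be 'median' or 'mean', got {self.center!r}")

    def smoothing(self) -> SmoothingConfig:
        return SmoothingConfig(
            window=self.window,
            polyorder=self.polyorder,
            domain_threshold=self.domain_threshold,
            peak_prominence=self.peak_prominence,
            region_pad=self.region_pad,
            min_domain_width=self.min_domain_width,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def with_overrides(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)
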