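"""Run configuration for the command-line pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import yaml

from .errors import SchemaError, ValidationError


@dataclass
class RunConfig:
    """Defaults and knobs shared by the CLI subcommands.

    Geometry defaults match a 9 mm static Franz cell; ``flux_window``
    selects the maximum-flux definition (``"interval"`` per-interval or
    ``"origin"`` since-application); ``qspr_intercept`` is the Potts-Guy
    constant (−6.3 for Kp in cm/s, −2.74 for cm/h); exclusion sets for
    the comparison regressions are explicit, never inferred.
    """

    area_cm2: float = 0.6
    receptor_volume_ml: float = 5.0
    donor_volume_ml: float = 1.0
    sample_volume_ml: float = 0.5
    flux_window: str = "interval"
    ss_window_h: tuple[float, float] = (2.0, 6.0)
    bootstrap_resamples: int = 10_000
    seed: int = 0
    qspr_intercept: float = -6.3
    exclude: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.flux_window not in ("interval", "origin"):
            raise ValidationError(f"unknown flux_window {self.flux_window!r}")
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError("config file must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "ss_window_h" in raw:
            raw["ss_window_h"] = tuple(raw["ss_window_h"])
        if "exclude" in raw:
            raw["exclude"] = frozenset(raw["exclude"])
        return cls(**raw)
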