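"""HPLC calibration fitting and inverse prediction of concentrations.

Detector response (peak area) is regressed on concentration by unweighted
ordinary least squares; receptor-fluid concentrations are then recovered
by inverting the fitted line. Detection limits follow the ICH convention
for instrumental methods: LOD = 3.3·σ/|slope| and LOQ = 10·σ/|slope|,
with σ the residual standard deviation of the calibration fit (n − 2
denominator). Back-calculated concentrations below the LOD are censored;
negative back-calculations are clamped to zero, since a receptor
concentration is a physical quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SchemaError, ValidationError

__all__ = [
    "CalibrationLevel",
    "CalibrationCurve",
    "fit_calibration",
    "inverse_predict",
    "load_calibration_levels",
    "write_calibration_fits",
]


@dataclass(frozen=True)
class CalibrationLevel:
    """One standard: nominal concentration (µg/mL) and detector response."""

    concentration: float
    response: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError(
                f"calibration concentration must be >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted response-vs-concentration line with its detection limits.

    slope/intercept are in detector units per (µg/mL) and detector units;
    ``lod``/``loq`` and the valid range are in µg/mL.
    """

    compound: str
    slope: float
    intercept: float
    r2: float
    residual_sd: float
    lod: float
    loq: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError(f"{self.compound}: slope must be nonzero")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValidationError(f"{self.compound}: r2 must lie in [0, 1], got {self.r2}")
        if not (0.0 <= self.lod <= self.loq):
            raise ValidationError(
                f"{self.compound}: need 0 <= lod <= loq, got lod={self.lod}, loq={self.loq}"
            )
        if not self.range_low < self.range_high:
            raise ValidationError(
                f"{self.compound}: range_low must be < range_high"
            )


def fit_calibration(
    levels: Sequence[CalibrationLevel],
    valid_range: tuple[float, float],
    compound: str = "",
) -> CalibrationCurve:
    """Fit a calibration line by ordinary least squares.

    Requires at least three levels spanning at least two distinct
    concentrations, all inside ``valid_range``. ``r2`` is the squared
    Pearson correlation between response and concentration; for an exact
    line (zero residual scatter) it is 1 by convention.

    Raises
    ------
    InsufficientDataError
        Fewer than three levels, or all concentrations identical.
    ValidationError
        A level outside the declared range.
    """
    low, high = valid_range
    if len(levels) < 3:
        raise InsufficientDataError(
            f"calibration needs >= 3 levels, got {len(levels)}"
        )
    conc = np.array([lv.concentration for lv in levels], dtype=float)
    resp = np.array([lv.response for lv in levels], dtype=float)
    if np.unique(conc).size < 2:
        raise InsufficientDataError("calibration needs >= 2 distinct concentrations")
    if conc.min() < low or conc.max() > high:
        raise ValidationError(
            f"calibration level outside declared range [{low}, {high}]"
        )

    fit = stats.linregress(conc, resp)
    residuals = resp - (fit.slope * conc + fit.intercept)
    residual_sd = float(np.sqrt(np.sum(residuals**2) / (conc.size - 2)))
    # Guard against r slightly outside [-1, 1] from rounding.
    r2 = min(float(fit.rvalue) ** 2, 1.0)
    lod = 3.3 * residual_sd / abs(fit.slope)
    loq = 10.0 * residual_sd / abs(fit.slope)
    return CalibrationCurve(
        compound=compound,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        residual_sd=residual_sd,
        lod=lod,
        loq=loq,
        range_low=low,
        range_high=high,
    )


def inverse_predict(
    curve: CalibrationCurve, response: float
) -> tuple[float, bool, bool]:
    """Back-calculate a concentration from a detector response.

    Returns ``(concentration, censored, extrapolated)``. The
    concentration is ``(response − intercept)/slope`` floored at zero;
    ``censored`` is set when it falls below the curve's LOD, and
    ``extrapolated`` when it exceeds the upper end of the calibrated
    range (the value is still returned).
    """
    concentration = (response - curve.intercept) / curve.slope
    if concentration < 0.0:
        concentration = 0.0
    censored = concentration < curve.lod
    extrapolated = concentration > curve.range_high
    return concentration, censored, extrapolated


def load_calibration_levels(path: str | PathLike) -> dict[str, list[CalibrationLevel]]:
    """Read ``compound,concentration_ug_per_ml,response_area`` CSV rows."""
    df = pd.read_csv(path)
    required = ("compound", "concentration_ug_per_ml", "response_area")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"calibration table is missing required column {col!r}")
    out: dict[str, list[CalibrationLevel]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["compound"]), []).append(
            CalibrationLevel(
                concentration=float(row["concentration_ug_per_ml"]),
                response=float(row["response_area"]),
            )
        )
    return out


def write_calibration_fits(
    curves: Iterable[CalibrationCurve], path: str | PathLike
) -> None:
    """Write fitted curves as ``calibration_fits.csv``."""
    df = pd.DataFrame(
        [
            {
                "compound": c.compound,
                "slope": c.slope,
                "intercept": c.intercept,
                "r2": c.r2,
                "residual_sd": c.residual_sd,
                "lod": c.lod,
                "loq": c.loq,
                "range_low": c.range_low,
                "range_high": c.range_high,
            }
            for c in curves
        ]
    )
    df.to_csv(path, index=False)
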