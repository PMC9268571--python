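"""Immobilized-artificial-membrane (IAM) chromatography processing.

IAM columns carry phosphatidylcholine analogues bonded to silica, so
retention on them reports a solute's affinity for membrane phospholipids
(phospholipophilicity). Because most solutes need organic modifier to
elute, the fully-aqueous retention factor kw is obtained by polycratic
extrapolation: isocratic retention factors k = (t_r − t_0)/t_0 are
measured at several acetonitrile volume fractions φ and log10 k is
extrapolated linearly to φ = 0 with the linear solvent-strength law

    log10 k(φ) = log10 kw − S·φ,

whose intercept is log kw and whose (negative) slope S is the solvent
strength. Replicate injections at the same φ are averaged before the
fit. Two stationary phases are supported, differing only in the
end-capping of the silica core: IAM.PC.MG and IAM.PC.DD2.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, SchemaError, ValidationError

__all__ = [
    "Phase",
    "IsocraticMeasurement",
    "LogKwFit",
    "retention_factor",
    "extrapolate_logkw",
    "cross_phase_regression",
    "load_iam_runs",
    "write_logkw_fits",
]


class Phase(str, Enum):
    """IAM stationary phase variants."""

    MG = "IAM.PC.MG"
    DD2 = "IAM.PC.DD2"


@dataclass(frozen=True)
class IsocraticMeasurement:
    """One isocratic injection: modifier fraction, retention and dead time.

    ``phi`` is the acetonitrile volume fraction as a number in (0, 1);
    ``t_r`` and ``t_0`` are the analyte retention time and the column
    dead time in minutes (t_0 from an unretained marker).
    """

    compound: str
    phase: Phase
    phi: float
    t_r: float
    t_0: float

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 1.0):
            raise ValidationError(
                f"{self.compound}: phi must lie in (0, 1), got {self.phi}"
            )
        if not self.t_0 > 0:
            raise ValidationError(f"{self.compound}: t_0 must be > 0")
        if self.t_r < self.t_0:
            raise ValidationError(
                f"{self.compound}: t_r ({self.t_r}) < t_0 ({self.t_0}); "
                "dead time likely mis-assigned"
            )


@dataclass(frozen=True)
class LogKwFit:
    """Polycratic fit for one compound on one phase: intercept is log kw."""

    compound: str
    phase: Phase
    log_kw: float
    slope: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("a polycratic fit needs >= 3 points")


def retention_factor(t_r: float, t_0: float) -> float:
    """Isocratic retention factor k = (t_r − t_0)/t_0."""
    if not t_0 > 0:
        raise ValidationError(f"t_0 must be > 0, got {t_0}")
    if t_r < t_0:
        raise ValidationError(
            f"t_r ({t_r}) < t_0 ({t_0}); dead time likely mis-assigned"
        )
    return (t_r - t_0) / t_0


def extrapolate_logkw(measurements: Sequence[IsocraticMeasurement]) -> LogKwFit:
    """Fit log10 k against φ and extrapolate to the fully aqueous phase.

    All measurements must belong to one compound × phase. Replicates at
    the same φ are averaged (on the log10 k scale) before the ordinary
    least-squares fit; at least three distinct φ values are required,
    and k must be positive everywhere for the logarithm to exist.

    Returns the fit with ``log_kw`` = intercept at φ = 0, the slope
    (expected negative: more modifier, less retention), the squared
    Pearson correlation of the averaged points, and the number of
    distinct φ levels used.
    """
    if not measurements:
        raise InsufficientDataError("no measurements given")
    compounds = {m.compound for m in measurements}
    phases = {m.phase for m in measurements}
    if len(compounds) != 1 or len(phases) != 1:
        raise ValidationError(
            "extrapolate_logkw expects a single compound x phase group; "
            f"got compounds {sorted(compounds)} phases {sorted(p.value for p in phases)}"
        )
    ks = [retention_factor(m.t_r, m.t_0) for m in measurements]
    if any(k <= 0 for k in ks):
        raise ValidationError(
            "retention factor must be > 0 at every phi (log k undefined at k = 0)"
        )
    logk_by_phi: dict[float, list[float]] = {}
    for m, k in zip(measurements, ks):
        logk_by_phi.setdefault(m.phi, []).append(np.log10(k))
    if len(logk_by_phi) < 3:
        raise InsufficientDataError(
            f"polycratic extrapolation needs >= 3 distinct phi, got {len(logk_by_phi)}"
        )
    phi = np.array(sorted(logk_by_phi))
    logk = np.array([np.mean(logk_by_phi[p]) for p in phi])
    fit = stats.linregress(phi, logk)
    return LogKwFit(
        compound=next(iter(compounds)),
        phase=next(iter(phases)),
        log_kw=float(fit.intercept),
        slope=float(fit.slope),
        r2=min(float(fit.rvalue) ** 2, 1.0),
        n_points=len(phi),
    )


def cross_phase_regression(
    pairs: Sequence[tuple[str, float, float]],
    exclude: frozenset[str] | set[str] = frozenset(),
) -> tuple[float, float, float, int]:
    """Regress one phase's log kw on the other's across compounds.

    ``pairs`` holds ``(compound, x, y)`` rows, conventionally x = log kw
    on IAM.PC.MG and y = log kw on IAM.PC.DD2. Compounds named in
    ``exclude`` are dropped first (exclusion is always explicit — e.g.
    an ionized analyte retained anomalously at the working pH). Returns
    ``(slope, intercept, r2, n)`` from OLS of y on x, with r² the
    squared Pearson correlation (hence symmetric in the two phases).
    """
    kept = [(c, x, y) for c, x, y in pairs if c not in exclude]
    if len(kept) < 3:
        raise InsufficientDataError(
            f"cross-phase regression needs >= 3 pairs after exclusion, got {len(kept)}"
        )
    x = np.array([p[1] for p in kept])
    y = np.array([p[2] for p in kept])
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), min(float(fit.rvalue) ** 2, 1.0), len(kept)


def load_iam_runs(path: str | PathLike) -> list[IsocraticMeasurement]:
    """Read an ``iam_runs.csv`` table of isocratic injections.

    Columns: ``compound, phase, phi_percent, tr_min, t0_min`` and an
    optional ``replicate``. ``phi_percent`` is in percent v/v and is
    divided by 100 on load.
    """
    df = pd.read_csv(path)
    required = ("compound", "phase", "phi_percent", "tr_min", "t0_min")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"iam_runs table is missing required column {col!r}")
    return [
        IsocraticMeasurement(
            compound=str(row["compound"]),
            phase=Phase(str(row["phase"])),
            phi=float(row["phi_percent"]) / 100.0,
            t_r=float(row["tr_min"]),
            t_0=float(row["t0_min"]),
        )
        for _, row in df.iterrows()
    ]


def write_logkw_fits(fits: Iterable[LogKwFit], path: str | PathLike) -> None:
    """Write fits as ``logkw_fits.csv``."""
    df = pd.DataFrame(
        [
            {
                "compound": f.compound,
                "phase": f.phase.value,
                "log_kw": f.log_kw,
                "slope": f.slope,
                "r2": f.r2,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )
    df.to_csv(path, index=False)
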