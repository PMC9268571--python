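"""Franz diffusion-cell permeation analysis.

A vertical static Franz cell holds a donor solution above a membrane
(here, skin) and a stirred receptor compartment below; aliquots drawn
from the receptor at scheduled times are assayed and immediately
replaced with fresh medium. This module turns those receptor
concentration-time series into the standard in-vitro permeation metrics:

* cumulative permeated amount Q(t), corrected for the mass removed with
  each aliquot: ``Q_n = V_r·C_n + V_s·Σ_{i<n} C_i``;
* flux per sampling interval, ``J_n = ΔQ/(A·Δt)`` in µg/cm²/h, and the
  maximum flux over intervals;
* steady-state flux from the linear late-time slope of Q(t);
* permeability coefficient ``Kp = J/Cd`` (cm/h) and its conventional
  log10(cm/s) form;
* percent of the applied dose recovered in the receptor fluid.

An analyte never observed above the assay's detection limit at any time
point is "not detected" (nd); nd propagates as NaN plus a ``detected``
flag, never as a zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError, ValidationError

__all__ = [
    "CellGeometry",
    "SamplePoint",
    "FranzRun",
    "PermeationResult",
    "ReplicateSummary",
    "cumulative_amounts",
    "flux_profile",
    "max_flux",
    "steady_state_flux",
    "permeability_coefficient",
    "kp_log_cm_per_s",
    "total_absorption_percent",
    "analyze_franz_run",
    "aggregate_replicates",
    "load_franz_runs",
    "write_permeation_summary",
]

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class CellGeometry:
    """Franz-cell geometry. Defaults match a 9 mm orifice static cell.

    area : effective diffusion area, cm² (default 0.6)
    receptor_volume : receptor compartment volume, mL (default 5.0)
    sample_volume : aliquot volume withdrawn and replaced at each time, mL
    donor_volume : applied donor solution volume, mL (default 1.0)
    """

    sample_volume: float
    area: float = 0.6
    receptor_volume: float = 5.0
    donor_volume: float = 1.0

    def __post_init__(self) -> None:
        for name in ("area", "receptor_volume", "donor_volume"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.sample_volume < 0:
            raise ValidationError("sample_volume must be >= 0")
        if self.sample_volume >= self.receptor_volume:
            raise ValidationError("sample_volume must be < receptor_volume")


class SamplePoint(NamedTuple):
    """One receptor aliquot: time (h), measured concentration (µg/mL), LOD flag."""

    time: float
    concentration: float
    censored: bool = False


@dataclass(frozen=True)
class FranzRun:
    """A single diffusion cell's measured receptor series."""

    cell_id: str
    compound: str
    geometry: CellGeometry
    donor_concentration: float  # Cd, µg/mL == µg/cm³
    samples: tuple[SamplePoint, ...]

    def __post_init__(self) -> None:
        if not self.donor_concentration > 0:
            raise ValidationError(
                f"{self.cell_id}: donor_concentration must be > 0"
            )
        times = [s.time for s in self.samples]
        if any(t <= 0 for t in times):
            raise ValidationError(f"{self.cell_id}: sampling times must be > 0")
        if any(b >= a for a, b in zip(times[1:], times)):
            raise ValidationError(
                f"{self.cell_id}: sampling times must be strictly increasing"
            )
        if any(s.concentration < 0 for s in self.samples):
            raise ValidationError(f"{self.cell_id}: concentrations must be >= 0")


@dataclass(frozen=True)
class PermeationResult:
    """Per-cell permeation metrics. NaN fields mean "not detected"."""

    cell_id: str
    compound: str
    donor_concentration: float
    times: np.ndarray  # h
    cumulative: np.ndarray  # Q, µg
    censored: np.ndarray  # bool per time point
    flux_profile: np.ndarray  # per-interval J, µg/cm²/h
    max_flux: float
    steady_state_flux: float
    kp_cm_per_h: float
    log_kp_cm_per_s: float
    percent_absorbed: float
    detected: bool


@dataclass(frozen=True)
class ReplicateSummary:
    """Across-replicate summary for one compound (one reported table row)."""

    compound: str
    n: int
    max_flux_mean: float
    max_flux_sd: float
    kp_cm_per_h: float
    log_kp_cm_per_s: float
    percent_median: float
    percent_ci_low: float
    percent_ci_high: float
    detected: bool


def cumulative_amounts(run: FranzRun) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative permeated amount at each sampling time.

    Applies the standard withdrawal/replacement correction for a fixed
    aliquot volume: the mass in the receptor now plus all mass previously
    carried away in aliquots,

        Q_n = V_r · C_n + V_s · Σ_{i<n} C_i   (µg).

    Censored concentrations contribute zero mass; the flag is carried
    through in the returned boolean array.

    Returns ``(times, Q, censored)`` as aligned numpy arrays.
    """
    times = np.array([s.time for s in run.samples], dtype=float)
    conc = np.array(
        [0.0 if s.censored else s.concentration for s in run.samples], dtype=float
    )
    censored = np.array([s.censored for s in run.samples], dtype=bool)
    v_r = run.geometry.receptor_volume
    v_s = run.geometry.sample_volume
    withdrawn = np.concatenate(([0.0], np.cumsum(conc)[:-1]))
    q = v_r * conc + v_s * withdrawn
    return times, q, censored


def flux_profile(times: np.ndarray, cumulative: np.ndarray, area: float) -> np.ndarray:
    """Per-interval flux J_n = (Q_n − Q_{n−1}) / (A·(t_n − t_{n−1})).

    The experiment starts at dose application, so the series is anchored
    at Q = 0, t = 0 and the first sampling interval is an ordinary one.
    """
    times = np.asarray(times, dtype=float)
    cumulative = np.asarray(cumulative, dtype=float)
    if times.size < 1:
        raise InsufficientDataError("flux_profile needs at least one interval")
    if not area > 0:
        raise ValidationError("area must be > 0")
    t_ext = np.concatenate(([0.0], times))
    if np.any(np.diff(t_ext) <= 0):
        raise ValidationError("sampling times must be strictly increasing and > 0")
    q_ext = np.concatenate(([0.0], cumulative))
    return np.diff(q_ext) / (area * np.diff(t_ext))


def max_flux(profile: Sequence[float]) -> float:
    """Maximum over the per-interval fluxes."""
    arr = np.asarray(profile, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("max_flux needs a non-empty flux profile")
    return float(np.max(arr))


def steady_state_flux(
    times: np.ndarray,
    cumulative: np.ndarray,
    area: float,
    window: tuple[float, float] = (2.0, 6.0),
) -> float:
    """Late-time flux from the linear slope of Q(t) inside ``window`` (h).

    Fits Q = a + b·t by least squares over the sampling times falling in
    the closed window and returns b/A. NaN when fewer than two points
    fall inside the window.
    """
    times = np.asarray(times, dtype=float)
    cumulative = np.asarray(cumulative, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if mask.sum() < 2:
        return math.nan
    slope = np.polyfit(times[mask], cumulative[mask], 1)[0]
    return float(slope) / area


def permeability_coefficient(flux: float, donor_concentration: float) -> float:
    """Kp = J / Cd, in cm/h (J in µg/cm²/h, Cd in µg/cm³)."""
    if not donor_concentration > 0:
        raise ValidationError("donor_concentration must be > 0")
    return flux / donor_concentration


def kp_log_cm_per_s(kp_cm_per_h: float) -> float:
    """Convert Kp from cm/h to the conventional log10(cm/s) scale.

    NaN (not detected) propagates as NaN; a nonpositive finite Kp is an
    error because its logarithm is undefined.
    """
    if math.isnan(kp_cm_per_h):
        return math.nan
    if kp_cm_per_h <= 0:
        raise ValidationError(f"kp must be > 0, got {kp_cm_per_h}")
    return math.log10(kp_cm_per_h / SECONDS_PER_HOUR)


def total_absorption_percent(amount_receptor: float, amount_applied: float) -> float:
    """Percent of the applied dose found in the receptor fluid.

    ``100 · amount_receptor / amount_applied``. Values above 100% signal
    a mass-balance violation: the value is capped at 100 and a warning
    is emitted.
    """
    if not amount_applied > 0:
        raise ValidationError("amount_applied must be > 0")
    if amount_receptor < 0:
        raise ValidationError("amount_receptor must be >= 0")
    percent = 100.0 * amount_receptor / amount_applied
    if percent > 100.0:
        warnings.warn(
            f"receptor amount exceeds applied dose ({percent:.1f}%); capped at 100",
            stacklevel=2,
        )
        percent = 100.0
    return percent


def analyze_franz_run(
    run: FranzRun,
    flux_mode: str = "interval",
    ss_window: tuple[float, float] = (2.0, 6.0),
) -> PermeationResult:
    """Full per-cell pipeline from measured concentrations to metrics.

    ``flux_mode`` selects the maximum-flux definition: ``"interval"``
    (default) takes the maximum per-interval flux, which resolves an
    early transient maximum; ``"origin"`` takes max over Q_n/(A·t_n),
    the average flux since application. Kp is computed from the maximum
    flux, and the steady-state flux over ``ss_window`` is reported
    alongside.
    """
    if flux_mode not in ("interval", "origin"):
        raise ValidationError(f"unknown flux_mode {flux_mode!r}")
    times, q, censored = cumulative_amounts(run)
    geometry = run.geometry
    detected = bool((~censored).any()) and bool(np.any(q > 0))

    profile = flux_profile(times, q, geometry.area)
    if not detected:
        jmax = math.nan
        kp = math.nan
        log_kp = math.nan
        percent = math.nan
        j_ss = math.nan
    else:
        if flux_mode == "interval":
            jmax = max_flux(profile)
        else:
            jmax = max_flux(q / (geometry.area * times))
        kp = permeability_coefficient(jmax, run.donor_concentration)
        log_kp = kp_log_cm_per_s(kp) if kp > 0 else math.nan
        applied = geometry.donor_volume * run.donor_concentration
        if q[-1] > applied:
            warnings.warn(
                f"{run.cell_id}: cumulative amount {q[-1]:.3g} µg exceeds the "
                f"applied dose {applied:.3g} µg (mass-balance violation)",
                stacklevel=2,
            )
        percent = total_absorption_percent(min(q[-1], applied), applied)
        j_ss = steady_state_flux(times, q, geometry.area, ss_window)

    return PermeationResult(
        cell_id=run.cell_id,
        compound=run.compound,
        donor_concentration=run.donor_concentration,
        times=times,
        cumulative=q,
        censored=censored,
        flux_profile=profile,
        max_flux=jmax,
        steady_state_flux=j_ss,
        kp_cm_per_h=kp,
        log_kp_cm_per_s=log_kp,
        percent_absorbed=percent,
        detected=detected,
    )


def aggregate_replicates(
    results: Sequence[PermeationResult],
    n_boot: int = 10_000,
    seed: int = 0,
) -> ReplicateSummary:
    """Summarise replicate cells of one compound.

    Mean ± SD (n − 1 denominator) of the per-cell maximum flux; Kp from
    the mean maximum flux over the shared donor concentration; median of
    percent absorbed with a seeded percentile-bootstrap 95% CI
    (``n_boot`` resamples, lower bound floored at 0). A compound with no
    detected replicate is reported as not detected (all-NaN row).
    """
    if len(results) < 1:
        raise InsufficientDataError("aggregate_replicates needs >= 1 replicate")
    compounds = {r.compound for r in results}
    if len(compounds) != 1:
        raise ValidationError(f"mixed compounds in replicate set: {sorted(compounds)}")
    compound = results[0].compound
    detected = [r for r in results if r.detected]
    if not detected:
        nan = math.nan
        return ReplicateSummary(
            compound, len(results), nan, nan, nan, nan, nan, nan, nan, False
        )

    fluxes = np.array([r.max_flux for r in detected])
    percents = np.array([r.percent_absorbed for r in detected])
    mean_flux = float(np.mean(fluxes))
    sd_flux = float(np.std(fluxes, ddof=1)) if fluxes.size > 1 else 0.0
    cd = detected[0].donor_concentration
    kp = permeability_coefficient(mean_flux, cd)
    log_kp = kp_log_cm_per_s(kp) if kp > 0 else math.nan

    rng = np.random.default_rng(seed)
    boot = np.median(
        rng.choice(percents, size=(n_boot, percents.size), replace=True), axis=1
    )
    ci_low = max(0.0, float(np.percentile(boot, 2.5)))
    ci_high = float(np.percentile(boot, 97.5))

    return ReplicateSummary(
        compound=compound,
        n=len(results),
        max_flux_mean=mean_flux,
        max_flux_sd=sd_flux,
        kp_cm_per_h=kp,
        log_kp_cm_per_s=log_kp,
        percent_median=float(np.median(percents)),
        percent_ci_low=ci_low,
        percent_ci_high=ci_high,
        detected=True,
    )


def load_franz_runs(
    raw_path: str | PathLike, meta: dict
) -> list[FranzRun]:
    """Build runs from a ``franz_raw.csv`` table plus a metadata mapping.

    The raw table needs columns ``cell_id, compound, time_h,
    concentration_ug_per_ml, censored``; the metadata mapping needs keys
    ``area_cm2, receptor_volume_ml, sample_volume_ml, donor_volume_ml,
    donor_concentration_ug_per_ml`` (the latter either a number applied
    to every cell, or a compound-keyed mapping).
    """
    df = pd.read_csv(raw_path)
    required = ("cell_id", "compound", "time_h", "concentration_ug_per_ml", "censored")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"franz_raw table is missing required column {col!r}")
    meta_keys = (
        "area_cm2",
        "receptor_volume_ml",
        "sample_volume_ml",
        "donor_volume_ml",
        "donor_concentration_ug_per_ml",
    )
    for key in meta_keys:
        if key not in meta:
            raise SchemaError(f"franz metadata is missing required key {key!r}")
    geometry = CellGeometry(
        area=float(meta["area_cm2"]),
        receptor_volume=float(meta["receptor_volume_ml"]),
        sample_volume=float(meta["sample_volume_ml"]),
        donor_volume=float(meta["donor_volume_ml"]),
    )
    cd_entry = meta["donor_concentration_ug_per_ml"]
    runs: list[FranzRun] = []
    for (cell_id, compound), group in df.groupby(["cell_id", "compound"], sort=False):
        group = group.sort_values("time_h")
        samples = tuple(
            SamplePoint(
                time=float(row["time_h"]),
                concentration=float(row["concentration_ug_per_ml"]),
                censored=bool(row["censored"]),
            )
            for _, row in group.iterrows()
        )
        cd = float(cd_entry[compound]) if isinstance(cd_entry, dict) else float(cd_entry)
        runs.append(
            FranzRun(
                cell_id=str(cell_id),
                compound=str(compound),
                geometry=geometry,
                donor_concentration=cd,
                samples=samples,
            )
        )
    return runs


def write_permeation_summary(
    summaries: Iterable[ReplicateSummary], path: str | PathLike
) -> None:
    """Write one row per compound as ``permeation_summary.csv``."""
    df = pd.DataFrame(
        [
            {
                "compound": s.compound,
                "max_flux_mean": s.max_flux_mean,
                "max_flux_sd": s.max_flux_sd,
                "kp_cm_per_h": s.kp_cm_per_h,
                "log_kp_cm_per_s": s.log_kp_cm_per_s,
                "percent_median": s.percent_median,
                "percent_ci_low": s.percent_ci_low,
                "percent_ci_high": s.percent_ci_high,
                "detected": s.detected,
            }
            for s in summaries
        ]
    )
    df.to_csv(path, index=False)
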