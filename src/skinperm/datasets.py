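"""Packaged reference tables for the eight-paraben benchmark dataset.

The package ships, as plain CSV, a published benchmark of p-hydroxybenzoic
acid (pHBA) and seven of its esters (methyl through benzyl paraben):
physicochemical properties, HPLC calibration parameters, Franz-cell
permeation summaries, IAM phospholipophilicity values on two stationary
phases, and experimental vs in-silico log Kp. Raw chromatograms and
receptor time series behind these summaries were never published, so the
summary rows are fixtures for comparison and inverse prediction — not
quantities this package can re-derive from raw data.

Not-detected entries are empty cells in the CSVs and surface as NaN with
``detected = False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import math

import pandas as pd

from .compounds import Compound, load_compound_table
from .permeation import ReplicateSummary
from .quantification import CalibrationCurve

__all__ = [
    "load_reference_compounds",
    "load_reference_calibration",
    "load_reference_permeation",
    "load_reference_logkw",
    "load_reference_logkp",
    "reference_tables",
    "ReferenceTables",
]


def _data_path(name: str):
    return resources.files("skinperm.data").joinpath(name)


def load_reference_compounds() -> list[Compound]:
    """The eight analytes with MW, log P, aqueous solubility and pKa."""
    with resources.as_file(_data_path("reference_compounds.csv")) as path:
        return load_compound_table(path)


def load_reference_calibration() -> dict[str, CalibrationCurve]:
    """Published calibration lines (slope, intercept, r²) per compound.

    The underlying level/response pairs were not published, so residual
    SD and the derived LOD/LOQ are unavailable and set to zero; these
    curves support inverse prediction only.
    """
    df = pd.read_csv(_data_path("reference_calibration.csv"))
    return {
        str(row["compound"]): CalibrationCurve(
            compound=str(row["compound"]),
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r2=float(row["r2"]),
            residual_sd=0.0,
            lod=0.0,
            loq=0.0,
            range_low=float(row["range_low"]),
            range_high=float(row["range_high"]),
        )
        for _, row in df.iterrows()
    }


def load_reference_permeation() -> list[ReplicateSummary]:
    """Franz-cell summary per compound: max flux ± SD, Kp, % permeation.

    Triplicate cells per compound (n = 3). Only pHBA, MP and EP crossed
    the membrane; the five longer esters are not-detected rows.
    """
    df = pd.read_csv(_data_path("reference_permeation.csv"))
    out = []
    for _, row in df.iterrows():
        detected = bool(row["detected"])
        kp = float(row["kp_cm_per_h"]) if detected else math.nan
        out.append(
            ReplicateSummary(
                compound=str(row["compound"]),
                n=3,
                max_flux_mean=float(row["max_flux_mean"]) if detected else math.nan,
                max_flux_sd=float(row["max_flux_sd"]) if detected else math.nan,
                kp_cm_per_h=kp,
                log_kp_cm_per_s=math.log10(kp / 3600.0) if detected else math.nan,
                percent_median=float(row["percent_median"]) if detected else math.nan,
                percent_ci_low=float(row["percent_ci_low"]) if detected else math.nan,
                percent_ci_high=float(row["percent_ci_high"]) if detected else math.nan,
                detected=detected,
            )
        )
    return out


def load_reference_logkw() -> list[tuple[str, float, float]]:
    """Measured log kw per compound as (name, IAM.PC.MG, IAM.PC.DD2)."""
    df = pd.read_csv(_data_path("reference_logkw.csv"))
    return [
        (str(r["compound"]), float(r["log_kw_mg"]), float(r["log_kw_dd2"]))
        for _, r in df.iterrows()
    ]


def load_reference_logkp() -> pd.DataFrame:
    """Experimental and in-silico log10 Kp (cm/s); NaN where not detected."""
    return pd.read_csv(_data_path("reference_logkp.csv"))


@dataclass(frozen=True)
class ReferenceTables:
    """The full benchmark bundle, one attribute per published table."""

    compounds: list[Compound]
    calibration: dict[str, CalibrationCurve]
    permeation: list[ReplicateSummary]
    logkw: list[tuple[str, float, float]]
    logkp: pd.DataFrame


def reference_tables() -> ReferenceTables:
    """Load every packaged reference table as typed records."""
    return ReferenceTables(
        compounds=load_reference_compounds(),
        calibration=load_reference_calibration(),
        permeation=load_reference_permeation(),
        logkw=load_reference_logkw(),
        logkp=load_reference_logkp(),
    )
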