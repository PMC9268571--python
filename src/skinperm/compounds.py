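"""Analyte physicochemical records and skin-sample barrier-integrity QC.

The compound table carries the inputs of every downstream stage: molar
mass and octanol-water log P feed the QSPR prediction, aqueous solubility
sets the saturated donor concentration of a Franz-cell run, and the
optional pKa marks ionizable analytes whose chromatographic behaviour
deviates from the neutral esters.

Skin-sample quality control follows the trans-epidermal water loss (TEWL)
convention: a membrane with TEWL at or above the threshold (default
10 g/m²/h) has a compromised barrier and is excluded before permeation
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "Compound",
    "SkinSample",
    "load_compound_table",
    "write_compound_table",
    "qc_tewl_filter",
]

_REQUIRED_COLUMNS = ("name", "mw_g_per_mol", "logp", "solubility_ug_per_ml")


@dataclass(frozen=True)
class Compound:
    """One analyte: identity plus the physicochemical properties used here.

    Parameters
    ----------
    name : str
        Short identifier, unique within a table (e.g. ``"MP"``).
    mw : float
        Molar mass, g/mol. Must be positive.
    logp : float
        n-Octanol-water partition coefficient, log10 units.
    solubility : float or None
        Aqueous solubility, µg/mL (numerically equal to mg/L).
    pka : float or None
        Acid dissociation constant, log10 units; ``None`` when the analyte
        has no ionizable group in the working pH range.
    annotation : str or None
        Free-text provenance flag (e.g. a suspected transcription error in
        the source of the log P value).
    """

    name: str
    mw: float
    logp: float
    solubility: float | None = None
    pka: float | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("compound name must be non-empty")
        if not self.mw > 0:
            raise ValidationError(f"{self.name}: mw must be > 0, got {self.mw}")
        if self.solubility is not None and not self.solubility > 0:
            raise ValidationError(
                f"{self.name}: solubility must be > 0 when present, got {self.solubility}"
            )


@dataclass(frozen=True)
class SkinSample:
    """A skin specimen with its trans-epidermal water loss reading (g/m²/h)."""

    sample_id: str
    tewl: float

    def __post_init__(self) -> None:
        if self.tewl < 0:
            raise ValidationError(
                f"{self.sample_id}: TEWL must be >= 0, got {self.tewl}"
            )


def load_compound_table(path: str | PathLike) -> list[Compound]:
    """Read a compound table from CSV, validating each row.

    The file must carry the columns ``name, mw_g_per_mol, logp,
    solubility_ug_per_ml``; ``pka`` and ``annotation`` are optional.
    Row order is preserved.

    Raises
    ------
    SchemaError
        When a required column is absent.
    ValidationError
        When a row fails a physical invariant or names collide; the
        message carries the zero-based row index.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"compound table is missing required column {col!r}")
    out: list[Compound] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        try:
            compound = Compound(
                name=str(row["name"]),
                mw=float(row["mw_g_per_mol"]),
                logp=float(row["logp"]),
                solubility=_optional_float(row["solubility_ug_per_ml"]),
                pka=_optional_float(row.get("pka")),
                annotation=_optional_str(row.get("annotation")),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {idx}: non-numeric field ({exc})") from exc
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        if compound.name in seen:
            raise ValidationError(f"row {idx}: duplicate compound name {compound.name!r}")
        seen.add(compound.name)
        out.append(compound)
    return out


def write_compound_table(compounds: Sequence[Compound], path: str | PathLike) -> None:
    """Write compounds back to CSV with the canonical column layout.

    Numeric fields survive a load/write/load round trip bit-exactly
    (pandas prints floats with ``repr`` round-trip precision).
    """
    df = pd.DataFrame(
        {
            "name": [c.name for c in compounds],
            "mw_g_per_mol": [c.mw for c in compounds],
            "logp": [c.logp for c in compounds],
            "solubility_ug_per_ml": [c.solubility for c in compounds],
            "pka": [c.pka for c in compounds],
            "annotation": [c.annotation for c in compounds],
        }
    )
    df.to_csv(path, index=False)


def qc_tewl_filter(
    samples: Sequence[SkinSample], threshold: float = 10.0
) -> tuple[list[SkinSample], list[SkinSample]]:
    """Partition skin samples by barrier integrity.

    A sample passes iff its TEWL is *strictly below* ``threshold``
    (g/m²/h); a reading exactly at the threshold is rejected. Order is
    preserved and every input sample lands in exactly one of the two
    returned lists.
    """
    if not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    passed: list[SkinSample] = []
    rejected: list[SkinSample] = []
    for sample in samples:
        (passed if sample.tewl < threshold else rejected).append(sample)
    return passed, rejected


def _optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def _optional_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)
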