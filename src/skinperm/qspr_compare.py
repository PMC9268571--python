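"""Potts-Guy skin-permeability prediction and cross-method comparison.

The Potts-Guy QSPR relates the stratum-corneum permeability coefficient
of a solute to its lipophilicity and molecular size:

    log10 Kp (cm/s) = 0.71·logP − 0.0061·MW − 6.3,

the published regression over the Flynn permeability dataset. The
intercept is exposed so the cm/h parameterisation (−2.74) can be chosen
instead. This module also carries the comparison machinery between
methods — in-silico predictions, chromatographic phospholipophilicity
(log kw IAM) and experimental Franz-cell log Kp — as explicit OLS fits
with the exclusion set recorded in the result, plus the Welch t-test
used for between-group significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "POTTS_GUY_LOGP_COEF",
    "POTTS_GUY_MW_COEF",
    "POTTS_GUY_INTERCEPT_CM_PER_S",
    "POTTS_GUY_INTERCEPT_CM_PER_H",
    "QsprPrediction",
    "MethodComparison",
    "potts_guy_logkp",
    "compare_logkw_vs_logkp",
    "welch_t_test",
    "write_predictions",
    "write_method_comparisons",
]

POTTS_GUY_LOGP_COEF = 0.71
POTTS_GUY_MW_COEF = -0.0061
POTTS_GUY_INTERCEPT_CM_PER_S = -6.3
POTTS_GUY_INTERCEPT_CM_PER_H = -2.74


@dataclass(frozen=True)
class QsprPrediction:
    """An in-silico log10 permeability coefficient for one compound."""

    compound: str
    log_kp_cm_per_s: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_kp_cm_per_s):
            raise ValidationError(f"{self.compound}: prediction must be finite")


@dataclass(frozen=True)
class MethodComparison:
    """An OLS comparison between two permeability-related scales."""

    x_label: str
    y_label: str
    pairs: tuple[tuple[str, float, float], ...]
    slope: float
    intercept: float
    r2: float
    excluded: frozenset[str] = field(default_factory=frozenset)

    @property
    def n(self) -> int:
        return len(self.pairs)


def potts_guy_logkp(
    logp: float, mw: float, intercept: float = POTTS_GUY_INTERCEPT_CM_PER_S
) -> float:
    """Predicted log10 Kp from log P and molar mass (g/mol).

    With the default intercept Kp is in cm/s; pass
    ``POTTS_GUY_INTERCEPT_CM_PER_H`` for cm/h. Increasing in logp,
    decreasing in mw.
    """
    if not mw > 0:
        raise ValidationError(f"mw must be > 0, got {mw}")
    return POTTS_GUY_LOGP_COEF * logp + POTTS_GUY_MW_COEF * mw + intercept


def compare_logkw_vs_logkp(
    logkw_by_compound: Mapping[str, float],
    predictions: Sequence[QsprPrediction],
    exclude: frozenset[str] | set[str] = frozenset(),
    x_label: str = "log_kw",
    y_label: str = "log_kp_cm_per_s",
) -> MethodComparison:
    """Regress predicted log Kp on chromatographic log kw.

    Matches compounds present in both inputs, drops the ``exclude`` set,
    and fits log Kp = a·log kw + b by OLS. Compounds whose experimental
    permeability is "not detected" simply do not appear in either input;
    nothing is imputed. Needs at least three matched pairs.
    """
    pred_by_compound = {p.compound: p.log_kp_cm_per_s for p in predictions}
    pairs = tuple(
        (name, logkw_by_compound[name], pred_by_compound[name])
        for name in logkw_by_compound
        if name in pred_by_compound and name not in exclude
    )
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"method comparison needs >= 3 matched compounds, got {len(pairs)}"
        )
    x = np.array([p[1] for p in pairs])
    y = np.array([p[2] for p in pairs])
    fit = stats.linregress(x, y)
    return MethodComparison(
        x_label=x_label,
        y_label=y_label,
        pairs=pairs,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=min(float(fit.rvalue) ** 2, 1.0),
        excluded=frozenset(exclude),
    )


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t-test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    Each group needs at least two values, and the pooled variance must
    be nonzero for the statistic to exist.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va + vb == 0:
        raise ValidationError("degenerate (zero) variance in both groups")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


def write_predictions(
    predictions: Sequence[QsprPrediction], path: str | PathLike
) -> None:
    """Write predictions as ``qspr_predictions.csv``."""
    pd.DataFrame(
        [
            {"compound": p.compound, "log_kp_pred_cm_per_s": p.log_kp_cm_per_s}
            for p in predictions
        ]
    ).to_csv(path, index=False)


def write_method_comparisons(
    comparisons: Sequence[MethodComparison], path: str | PathLike
) -> None:
    """Write comparison summaries as ``method_comparison.csv``."""
    pd.DataFrame(
        [
            {
                "x_label": c.x_label,
                "y_label": c.y_label,
                "n": c.n,
                "slope": c.slope,
                "intercept": c.intercept,
                "r2": c.r2,
                "excluded": ";".join(sorted(c.excluded)),
            }
            for c in comparisons
        ]
    ).to_csv(path, index=False)
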