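"""Analytical method-validation statistics.

Covers the quality checks run before residue data are trusted:
linear calibration curves (instrument response vs concentration),
spike-recovery rate and relative standard deviation (RSD), the
solvent-vs-matrix matrix effect, and the screening rule that
establishes the method limit of quantification (LOQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CalibrationCurve",
    "LinearCalibration",
    "fit_calibration",
    "MatrixEffect",
    "matrix_effect",
    "RecoveryResult",
    "compute_recovery",
    "LOQScreen",
    "screen_loq",
]

#: |ME| at or above this percentage is conventionally called significant.
MATRIX_EFFECT_THRESHOLD = 20.0

#: Default acceptability band for mean recovery (percent) and RSD cap.
DEFAULT_RECOVERY_BAND = (70.0, 120.0)
DEFAULT_RSD_MAX = 20.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear response curve for a compound in solvent or matrix."""

    compound: str
    medium: str  # "solvent" or "matrix"
    slope: float
    intercept: float
    correlation: float
    levels: tuple = ()

    def __post_init__(self) -> None:
        if self.medium not in ("solvent", "matrix"):
            raise ValueError(f"medium must be 'solvent' or 'matrix', got {self.medium!r}")
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("slope must be finite and nonzero for a usable curve")
        if abs(self.correlation) > 1 + 1e-12:
            raise ValueError("correlation must lie in [-1, 1]")

    def predict_response(self, level: float) -> float:
        return self.slope * level + self.intercept


class LinearCalibration(BaseEstimator):
    """Ordinary least-squares calibration line, response = slope*conc + b.

    Attributes (after fit): ``slope_``, ``intercept_``, ``correlation_``
    (Pearson r), ``levels_``.
    """

    def fit(self, levels, responses) -> "LinearCalibration":
        x = np.asarray(levels, dtype=float)
        y = np.asarray(responses, dtype=float)
        if x.shape != y.shape:
            raise ValueError("levels and responses must have equal length")
        if np.unique(x).size < 3:
            raise ValueError(
                f"need at least 3 distinct calibration levels, got {np.unique(x).size}"
            )
        if np.ptp(y) == 0:
            raise ValueError("constant responses: degenerate zero-slope calibration")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.correlation_ = float(res.rvalue)
        self.levels_ = tuple(x.tolist())
        return self

    def predict(self, levels) -> np.ndarray:
        if not hasattr(self, "slope_"):
            raise ValueError("LinearCalibration is not fitted yet; call fit first")
        return self.slope_ * np.asarray(levels, dtype=float) + self.intercept_


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    compound: str = "",
    medium: str = "solvent",
) -> CalibrationCurve:
    """Fit an OLS calibration line and return it as a :class:`CalibrationCurve`."""
    est = LinearCalibration().fit(levels, responses)
    return CalibrationCurve(
        compound=compound,
        medium=medium,
        slope=est.slope_,
        intercept=est.intercept_,
        correlation=est.correlation_,
        levels=est.levels_,
    )


@dataclass(frozen=True)
class MatrixEffect:
    """Signed matrix effect with its magnitude and significance flag."""

    percent: float
    magnitude: float
    significant: bool


def matrix_effect(
    matrix_slope: float,
    solvent_slope: float,
    threshold: float = MATRIX_EFFECT_THRESHOLD,
) -> MatrixEffect:
    """Matrix effect ME% = (K1/K2 - 1) * 100.

    K1 is the matrix calibration slope, K2 the solvent slope.  The signed
    value is primary; the magnitude is reported alongside because residue
    studies conventionally print |ME|, with |ME| >= 20% flagged as a
    significant matrix effect.
    """
    if solvent_slope == 0:
        raise ZeroDivisionError("solvent slope must be nonzero")
    me = (matrix_slope / solvent_slope - 1.0) * 100.0
    # tiny tolerance so a mathematically exact 20% lands on the boundary
    return MatrixEffect(
        percent=me, magnitude=abs(me), significant=abs(me) >= threshold - 1e-9
    )


@dataclass(frozen=True)
class RecoveryResult:
    """Mean recovery and RSD at one spike level."""

    compound: str
    spike_level: float
    mean_recovery: float  # percent
    rsd: float  # percent, sample (n-1) standard deviation
    n: int


def compute_recovery(
    measured: Sequence[float],
    spike_level: float,
    compound: str = "",
) -> RecoveryResult:
    """Recovery statistics for replicate measurements of a spiked sample.

    mean_recovery = 100 * mean(measured) / spike_level;
    RSD = 100 * sd(measured) / mean(measured) with the sample (n-1) SD.
    """
    x = np.asarray(measured, dtype=float)
    if spike_level <= 0:
        raise ValueError(f"spike level must be positive, got {spike_level}")
    if x.size < 2:
        raise ValueError(f"need at least 2 measurements for recovery/RSD, got {x.size}")
    mean = float(x.mean())
    return RecoveryResult(
        compound=compound,
        spike_level=float(spike_level),
        mean_recovery=100.0 * mean / spike_level,
        rsd=100.0 * float(x.std(ddof=1)) / mean,
        n=int(x.size),
    )


@dataclass(frozen=True)
class LOQScreen:
    """Outcome of LOQ screening over the tested spike levels."""

    loq: float | None
    established: bool
    passing_levels: tuple = ()

    def __bool__(self) -> bool:  # truthy iff an LOQ was established
        return self.established


def screen_loq(
    recoveries: Sequence[RecoveryResult],
    recovery_band: tuple[float, float] = DEFAULT_RECOVERY_BAND,
    rsd_max: float = DEFAULT_RSD_MAX,
) -> LOQScreen:
    """Lowest spike level whose recovery and RSD meet the acceptance rule.

    A level passes when its mean recovery lies inside ``recovery_band``
    (default 70-120%) and its RSD does not exceed ``rsd_max`` (default
    20%).  When no level passes the result reports ``established=False``
    rather than raising: "no LOQ establishable" is a legitimate outcome.
    """
    if not recoveries:
        raise ValueError("need at least one spike level to screen for an LOQ")
    lo, hi = recovery_band
    passing = sorted(
        r.spike_level
        for r in recoveries
        if lo <= r.mean_recovery <= hi and r.rsd <= rsd_max
    )
    if not passing:
        return LOQScreen(loq=None, established=False)
    return LOQScreen(loq=passing[0], established=True, passing_levels=tuple(passing))


def validation_report(calibration: pd.DataFrame, recovery: pd.DataFrame) -> pd.DataFrame:
    """Full method-validation summary from calibration and recovery tables.

    ``calibration`` columns: compound, medium, level_mg_per_L, response.
    ``recovery`` columns: compound, spike_mg_per_kg, replicate,
    measured_mg_per_kg.  Returns a long table (compound, metric, key,
    value) covering curve parameters, matrix effects, per-level recovery
    and the screened LOQ.
    """
    rows: list[dict] = []
    slopes: dict[tuple[str, str], float] = {}
    for (compound, medium), grp in calibration.groupby(["compound", "medium"], sort=True):
        curve = fit_calibration(
            grp["level_mg_per_L"], grp["response"], compound=str(compound), medium=str(medium)
        )
        slopes[(str(compound), str(medium))] = curve.slope
        for key, value in (
            ("slope", curve.slope),
            ("intercept", curve.intercept),
            ("correlation", curve.correlation),
        ):
            rows.append(
                {"compound": compound, "metric": f"calibration_{key}", "key": medium, "value": value}
            )
    for compound in sorted({c for c, _ in slopes}):
        if (compound, "matrix") in slopes and (compound, "solvent") in slopes:
            me = matrix_effect(slopes[(compound, "matrix")], slopes[(compound, "solvent")])
            rows.append(
                {"compound": compound, "metric": "matrix_effect_percent", "key": "signed", "value": me.percent}
            )
            rows.append(
                {"compound": compound, "metric": "matrix_effect_percent", "key": "magnitude", "value": me.magnitude}
            )
            rows.append(
                {"compound": compound, "metric": "matrix_effect_significant", "key": "flag", "value": float(me.significant)}
            )
    for compound, comp_grp in recovery.groupby("compound", sort=True):
        results = []
        for level, grp in comp_grp.groupby("spike_mg_per_kg", sort=True):
            r = compute_recovery(grp["measured_mg_per_kg"], float(level), compound=str(compound))
            results.append(r)
            rows.append(
                {"compound": compound, "metric": "mean_recovery_percent", "key": f"{level:g}", "value": r.mean_recovery}
            )
            rows.append(
                {"compound": compound, "metric": "rsd_percent", "key": f"{level:g}", "value": r.rsd}
            )
        screen = screen_loq(results)
        rows.append(
            {
                "compound": compound,
                "metric": "loq_mg_per_kg",
                "key": "screened",
                "value": screen.loq if screen.established else float("nan"),
            }
        )
    return pd.DataFrame(rows)
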