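"""First-order dissipation kinetics for pesticide residues.

Residue decline after the last application is modelled as single
first-order decay,

    C(t) = C0 * exp(-k * t),

with C0 the initial deposit (mg/kg), k the rate constant (1/day) and
half-life T1/2 = ln(2)/k.  Fitting is log-linear ordinary least squares
on ln C(t) vs t, the standard convention in supervised residue trials;
it is exactly invertible on noiseless data.  A nonlinear refinement
(least squares on the original scale) is available as an option.

Observations below the limit of quantification (LOQ) are censored;
three substitution policies are supported: ``drop`` (exclude the
point), ``half_loq`` (substitute LOQ/2, the default) and ``loq``
(substitute the LOQ itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "CENSOR_POLICIES",
    "DissipationSeries",
    "DissipationFit",
    "FirstOrderDecay",
    "fit_first_order",
    "half_life",
    "dissipation_rate",
    "apply_censor_policy",
]

CENSOR_POLICIES = ("drop", "half_loq", "loq")


@dataclass
class DissipationSeries:
    """A residue-vs-time series for one compound at one trial site.

    ``residues`` keeps the recorded numeric value for every point, also
    for censored (< LOQ) ones, so censoring policies can be compared.
    """

    compound: str
    site: str
    days: np.ndarray
    residues: np.ndarray
    censored: np.ndarray = field(default=None)  # type: ignore[assignment]
    loq: float = 0.0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.residues = np.asarray(self.residues, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.days.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (self.days.shape == self.residues.shape == self.censored.shape):
            raise ValueError("days, residues and censored must have equal length")
        if self.days.size and self.days.min() < 0:
            raise ValueError("days must be non-negative")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.residues.size and self.residues.min() < 0:
            raise ValueError("residues must be non-negative")
        if self.loq < 0:
            raise ValueError("loq must be non-negative")

    def __len__(self) -> int:
        return self.days.size

    def to_frame(self) -> pd.DataFrame:
        """Long-format table matching the decay CSV schema."""
        return pd.DataFrame(
            {
                "compound": self.compound,
                "site": self.site,
                "day": self.days,
                "residue_mg_per_kg": self.residues,
                "censored": self.censored.astype(int),
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame, loq: float = 0.05) -> list["DissipationSeries"]:
        """Split a decay table into one series per (compound, site)."""
        out = []
        for (compound, site), grp in df.groupby(["compound", "site"], sort=True):
            grp = grp.sort_values("day")
            out.append(
                DissipationSeries(
                    compound=str(compound),
                    site=str(site),
                    days=grp["day"].to_numpy(),
                    residues=grp["residue_mg_per_kg"].to_numpy(),
                    censored=grp["censored"].to_numpy().astype(bool),
                    loq=loq,
                )
            )
        return out


@dataclass(frozen=True)
class DissipationFit:
    """Fitted first-order parameters for one series."""

    c0_hat: float
    k_hat: float
    half_life: float
    r_squared: float
    n_used: int
    half_life_defined: bool = True


def apply_censor_policy(
    values: np.ndarray,
    censored: np.ndarray,
    policy: str,
    loq: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (mask_of_kept_points, substituted_values) under a policy."""
    if policy not in CENSOR_POLICIES:
        raise ValueError(f"unknown censor policy {policy!r}; expected one of {CENSOR_POLICIES}")
    values = np.asarray(values, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    keep = np.ones(values.shape, dtype=bool)
    out = values.copy()
    if policy == "drop":
        keep = ~censored
    elif policy == "half_loq":
        out[censored] = loq / 2.0
    else:  # "loq"
        out[censored] = loq
    return keep, out


class FirstOrderDecay(BaseEstimator):
    """First-order residue-decay model fit by log-linear least squares.

    Parameters
    ----------
    censor_policy : {"drop", "half_loq", "loq"}, default "half_loq"
        Handling of below-LOQ observations before fitting.
    nonlinear : bool, default False
        Refine the log-linear estimates by nonlinear least squares on
        the original concentration scale.

    Attributes
    ----------
    c0_ : float
        Estimated initial deposit, mg/kg (exp of the log-line intercept).
    k_ : float
        Estimated rate constant, 1/day (negative of the log-line slope).
    half_life_ : float
        ln(2)/k_, days; NaN when the fitted slope is non-negative.
    half_life_defined_ : bool
        False when the series does not decline (k_ <= 0).
    r_squared_ : float
        Coefficient of determination of the log-linear fit.
    n_used_ : int
        Number of observations entering the fit after censor handling.
    """

    def __init__(self, censor_policy: str = "half_loq", nonlinear: bool = False):
        self.censor_policy = censor_policy
        self.nonlinear = nonlinear

    def fit(self, days, residues, censored=None, loq: float = 0.0) -> "FirstOrderDecay":
        t = np.asarray(days, dtype=float)
        y = np.asarray(residues, dtype=float)
        if censored is None:
            censored = np.zeros(t.shape, dtype=bool)
        keep, y_sub = apply_censor_policy(y, censored, self.censor_policy, loq)
        t_use, y_use = t[keep], y_sub[keep]
        if t_use.size < 3:
            raise ValueError(
                f"need at least 3 usable points to fit first-order decay, got {t_use.size}"
            )
        if np.unique(t_use).size < 2:
            raise ValueError("need at least 2 distinct sampling days")
        if np.any(y_use <= 0):
            raise ValueError(
                "non-positive residue after censor substitution; cannot log-transform"
            )
        res = stats.linregress(t_use, np.log(y_use))
        c0 = math.exp(res.intercept)
        k = -res.slope
        r2 = float(res.rvalue**2)
        if self.nonlinear and k > 0:
            popt, _ = optimize.curve_fit(
                lambda tt, c0_, k_: c0_ * np.exp(-k_ * tt),
                t_use,
                y_use,
                p0=[c0, k],
                maxfev=10_000,
            )
            c0, k = float(popt[0]), float(popt[1])
            ss_res = float(np.sum((y_use - c0 * np.exp(-k * t_use)) ** 2))
            ss_tot = float(np.sum((y_use - y_use.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.c0_ = float(c0)
        self.k_ = float(k)
        self.half_life_defined_ = k > 0
        self.half_life_ = math.log(2) / k if k > 0 else math.nan
        self.r_squared_ = r2
        self.n_used_ = int(t_use.size)
        return self

    def predict(self, days) -> np.ndarray:
        """Predicted residue concentration C0*exp(-k t), mg/kg."""
        if not hasattr(self, "k_"):
            raise ValueError("FirstOrderDecay is not fitted yet; call fit first")
        t = np.asarray(days, dtype=float)
        return self.c0_ * np.exp(-self.k_ * t)

    def to_result(self) -> DissipationFit:
        if not hasattr(self, "k_"):
            raise ValueError("FirstOrderDecay is not fitted yet; call fit first")
        return DissipationFit(
            c0_hat=self.c0_,
            k_hat=self.k_,
            half_life=self.half_life_,
            r_squared=self.r_squared_,
            n_used=self.n_used_,
            half_life_defined=self.half_life_defined_,
        )


def fit_first_order(
    series: DissipationSeries,
    censor_policy: str = "half_loq",
    nonlinear: bool = False,
) -> DissipationFit:
    """Fit C(t) = C0 exp(-kt) to one series; see :class:`FirstOrderDecay`."""
    est = FirstOrderDecay(censor_policy=censor_policy, nonlinear=nonlinear)
    est.fit(series.days, series.residues, censored=series.censored, loq=series.loq)
    return est.to_result()


def half_life(k: float) -> float:
    """Half-life T1/2 = ln(2)/k in days, for rate constant k > 0 (1/day)."""
    if k <= 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return math.log(2) / k


def dissipation_rate(c0: float, ct: float) -> float:
    """Dissipation percentage 100*(C0 - Ct)/C0 between application and day t."""
    if c0 <= 0:
        raise ValueError(f"initial concentration must be positive, got {c0}")
    if ct < 0:
        raise ValueError(f"residue concentration must be non-negative, got {ct}")
    return 100.0 * (c0 - ct) / c0


def summarize_fits(series_list: list[DissipationSeries], censor_policy: str = "half_loq") -> pd.DataFrame:
    """Fit every series and return the per-site summary table."""
    rows = []
    for s in series_list:
        f = fit_first_order(s, censor_policy=censor_policy)
        rows.append(
            {
                "compound": s.compound,
                "site": s.site,
                "c0_hat": f.c0_hat,
                "k_hat_per_day": f.k_hat,
                "half_life_days": f.half_life,
                "r_squared": f.r_squared,
                "n_used": f.n_used,
            }
        )
    return pd.DataFrame(rows)
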