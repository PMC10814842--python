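"""Probabilistic (Monte-Carlo) cumulative dietary-exposure model.

Instead of single point values (HR or STMR), consumption x and residue
concentration c are described by lognormal distributions fitted to the
survey and trial data, and per-capita exposure is resampled:

    y_i = sum_k x_ik * c_ik / bw_i        (mg/kg bw/day)

over the k registered foods, with bw_i the subgroup bodyweight treated
as a constant divisor.  Each Monte-Carlo iteration draws x and c
independently from their fitted lognormals; the resulting exposure
distribution is summarised as empirical percentiles (P50 ... P99.9)
expressed as a percentage of the ADI (chronic) or ARfD (acute).

For a single food the model has a closed form: y is lognormal with
mu = mu_x + mu_c - ln(bw) and sigma = sqrt(sigma_x^2 + sigma_c^2),
which serves as an exact oracle for the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .deterministic import PopulationSubgroup, ToxicologyReference
from .dissipation import CENSOR_POLICIES

__all__ = [
    "DEFAULT_PERCENTILE_LEVELS",
    "LognormalParams",
    "fit_lognormal",
    "ExposureSimulation",
    "simulate_exposure",
    "ExposureModel",
    "PercentileReport",
    "percentile_report",
    "stratified_run",
    "parse_percentile_label",
]

DEFAULT_PERCENTILE_LEVELS = ("P50", "P75", "P90", "P95", "P97.5", "P99", "P99.9")


def parse_percentile_label(label: str) -> float:
    """Map a 'P95'-style label to the quantile fraction 0.95."""
    text = label.strip().lstrip("Pp")
    q = float(text) / 100.0
    if not 0.0 < q < 1.0:
        raise ValueError(f"percentile label {label!r} outside (0, 100)")
    return q


@dataclass(frozen=True)
class LognormalParams:
    """Log-scale location/scale of a fitted lognormal distribution."""

    mu: float
    sigma: float
    n_fit: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def quantile(self, q: float) -> float:
        """Closed-form quantile exp(mu + sigma * Phi^-1(q))."""
        from scipy.stats import norm

        return math.exp(self.mu + self.sigma * norm.ppf(q))


def fit_lognormal(
    observations: Sequence[float],
    censored: Sequence[bool] | None = None,
    censor_policy: str = "half_loq",
    loq: float | None = None,
) -> LognormalParams:
    """Maximum-likelihood lognormal fit: mean and SD of the log data.

    Censored (< LOQ) observations are substituted before the log
    transform: dropped, or replaced by LOQ/2 or LOQ.  When ``loq`` is
    None each censored observation's stored value is treated as its own
    reporting limit (the usual convention when "<LOQ" rows record the
    LOQ as the value).
    """
    if censor_policy not in CENSOR_POLICIES:
        raise ValueError(f"unknown censor policy {censor_policy!r}")
    x = np.asarray(observations, dtype=float)
    if censored is None:
        cen = np.zeros(x.shape, dtype=bool)
    else:
        cen = np.asarray(censored, dtype=bool)
    if x.shape != cen.shape:
        raise ValueError("observations and censored flags must have equal length")
    if censor_policy == "drop":
        x = x[~cen]
    else:
        limits = np.where(np.isnan(x), np.nan, x) if loq is None else np.full(x.shape, loq)
        sub = limits / 2.0 if censor_policy == "half_loq" else limits
        x = np.where(cen, sub, x)
    if x.size < 2:
        raise ValueError(f"need at least 2 usable observations, got {x.size}")
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("non-positive or non-finite value after censor substitution")
    logs = np.log(x)
    return LognormalParams(
        mu=float(logs.mean()),
        sigma=float(logs.std(ddof=0)),  # MLE scale
        n_fit=int(x.size),
    )


@dataclass
class ExposureSimulation:
    """One subgroup's Monte-Carlo exposure run (possibly multi-food)."""

    subgroup: PopulationSubgroup
    consumption_dists: list[LognormalParams]
    residue_dists: list[LognormalParams]
    n_iter: int = 1000
    seed: int | np.random.SeedSequence = 0
    samples: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.consumption_dists) != len(self.residue_dists):
            raise ValueError("need one consumption/residue distribution pair per food")
        if not self.consumption_dists:
            raise ValueError("need at least one food")
        if self.n_iter < 1:
            raise ValueError(f"n_iter must be >= 1, got {self.n_iter}")


def simulate_exposure(sim: ExposureSimulation) -> ExposureSimulation:
    """Run the Monte-Carlo sampler and return the simulation with samples.

    Per iteration, consumption x_k and residue c_k are drawn
    independently for each food and y = sum_k x_k*c_k / bw.  The draw
    order (all x for food 1, all c for food 1, food 2, ...) is fixed so
    a given seed is bit-reproducible.
    """
    rng = np.random.default_rng(sim.seed)
    bw = sim.subgroup.bw
    total = np.zeros(sim.n_iter)
    for cons, resid in zip(sim.consumption_dists, sim.residue_dists):
        x = rng.lognormal(cons.mu, cons.sigma, size=sim.n_iter)
        c = rng.lognormal(resid.mu, resid.sigma, size=sim.n_iter)
        total += x * c
    return replace(sim, samples=total / bw)


class ExposureModel(BaseEstimator):
    """Single-food Monte-Carlo exposure estimator.

    fit() learns lognormal consumption and residue distributions from
    raw observations; sample() draws the exposure distribution for a
    subgroup.

    Parameters
    ----------
    n_iter : int, default 1000
        Monte-Carlo iterations per run.
    seed : int or None
        Seed for the sampler; None leaves seeding to the caller.
    censor_policy : {"drop", "half_loq", "loq"}
        Below-LOQ handling when fitting the residue distribution.
    """

    def __init__(self, n_iter: int = 1000, seed: int | None = None, censor_policy: str = "half_loq"):
        self.n_iter = n_iter
        self.seed = seed
        self.censor_policy = censor_policy

    def fit(
        self,
        consumption,
        residues,
        residue_censored=None,
        loq: float | None = None,
    ) -> "ExposureModel":
        self.consumption_dist_ = fit_lognormal(consumption)
        self.residue_dist_ = fit_lognormal(
            residues, censored=residue_censored, censor_policy=self.censor_policy, loq=loq
        )
        return self

    def sample(self, subgroup: PopulationSubgroup, seed=None) -> np.ndarray:
        """Draw n_iter exposures (mg/kg bw/day) for the subgroup."""
        if not hasattr(self, "consumption_dist_"):
            raise ValueError("ExposureModel is not fitted yet; call fit first")
        sim = ExposureSimulation(
            subgroup=subgroup,
            consumption_dists=[self.consumption_dist_],
            residue_dists=[self.residue_dist_],
            n_iter=self.n_iter,
            seed=self.seed if seed is None else seed,
        )
        return simulate_exposure(sim).samples

    def exposure_quantile(self, subgroup: PopulationSubgroup, q: float) -> float:
        """Closed-form single-food quantile of the exposure lognormal."""
        if not hasattr(self, "consumption_dist_"):
            raise ValueError("ExposureModel is not fitted yet; call fit first")
        combined = LognormalParams(
            mu=self.consumption_dist_.mu + self.residue_dist_.mu - math.log(subgroup.bw),
            sigma=math.hypot(self.consumption_dist_.sigma, self.residue_dist_.sigma),
        )
        return combined.quantile(q)


@dataclass(frozen=True)
class PercentileReport:
    """Exposure percentiles as percent of the reference dose."""

    subgroup: str
    compound: str
    levels: tuple
    values: tuple  # percent of ADI or ARfD, non-decreasing in level

    def to_frame(self, mode: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subgroup": self.subgroup,
                "compound": self.compound,
                "mode": mode,
                "percentile": list(self.levels),
                "percent_of_reference": list(self.values),
            }
        )


def percentile_report(
    samples,
    reference: float,
    levels: Iterable[str] = DEFAULT_PERCENTILE_LEVELS,
    subgroup: str = "",
    compound: str = "",
) -> PercentileReport:
    """Empirical exposure quantiles as percent of ADI or ARfD.

    Quantiles use linear interpolation between order statistics.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot report percentiles of an empty sample")
    if reference <= 0:
        raise ValueError(f"reference dose must be positive, got {reference}")
    labels = tuple(levels)
    qs = sorted((parse_percentile_label(lv), lv) for lv in labels)
    quant = np.quantile(x, [q for q, _ in qs], method="linear")
    by_label = {lv: 100.0 * v / reference for (_, lv), v in zip(qs, quant)}
    return PercentileReport(
        subgroup=subgroup,
        compound=compound,
        levels=labels,
        values=tuple(by_label[lv] for lv in labels),
    )


def expected_tail_count(level: str, n_iter: int) -> float:
    """Expected number of draws above the requested percentile."""
    return n_iter * (1.0 - parse_percentile_label(level))


def stratified_run(
    subgroups: Sequence[PopulationSubgroup],
    residue_data: pd.DataFrame,
    consumption_data: pd.DataFrame,
    toxicology: Sequence[ToxicologyReference],
    mode: str = "chronic",
    n_iter: int = 1000,
    seed: int = 0,
    levels: Iterable[str] = DEFAULT_PERCENTILE_LEVELS,
    censor_policy: str = "half_loq",
    loq: float | None = None,
) -> tuple[list[PercentileReport], dict[str, str]]:
    """One percentile report per subgroup x compound.

    ``residue_data`` columns: compound, residue_mg_per_kg, censored.
    ``consumption_data`` columns: subgroup, intake_kg_per_day, bw_kg.
    Acute mode references the ARfD, chronic mode the ADI.  A subgroup
    with missing data is recorded in the returned error map and the run
    continues.  Each compound's random stream derives from (seed,
    compound index) and is shared across subgroups, so identical
    subgroups produce identical reports.
    """
    if mode not in ("acute", "chronic"):
        raise ValueError(f"mode must be 'acute' or 'chronic', got {mode!r}")
    labels = tuple(levels)
    tox = {t.compound: t for t in toxicology}
    compounds = sorted(residue_data["compound"].unique())
    reports: list[PercentileReport] = []
    errors: dict[str, str] = {}
    for sg in subgroups:
        rows = consumption_data[consumption_data["subgroup"] == sg.name]
        if rows.empty:
            errors[sg.name] = f"no consumption data for subgroup {sg.name!r}"
            continue
        try:
            cons_dist = fit_lognormal(rows["intake_kg_per_day"])
        except ValueError as exc:
            errors[sg.name] = str(exc)
            continue
        for j, compound in enumerate(compounds):
            if compound not in tox:
                errors[compound] = f"no toxicology reference for compound {compound!r}"
                continue
            comp_rows = residue_data[residue_data["compound"] == compound]
            resid_dist = fit_lognormal(
                comp_rows["residue_mg_per_kg"],
                censored=comp_rows["censored"].astype(bool),
                censor_policy=censor_policy,
                loq=loq,
            )
            sim = simulate_exposure(
                ExposureSimulation(
                    subgroup=sg,
                    consumption_dists=[cons_dist],
                    residue_dists=[resid_dist],
                    n_iter=n_iter,
                    seed=np.random.SeedSequence(entropy=seed, spawn_key=(j,)),
                )
            )
            ref = tox[compound].arfd if mode == "acute" else tox[compound].adi
            reports.append(
                percentile_report(
                    sim.samples, ref, levels=labels, subgroup=sg.name, compound=str(compound)
                )
            )
    return reports, errors
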