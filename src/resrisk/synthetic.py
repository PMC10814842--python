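"""Synthetic study-shaped data with known ground truth.

Emulates the raw tables a supervised grape residue trial and a national
consumption survey would yield — first-order decay series with
multiplicative lognormal measurement noise and LOQ censoring,
spike-recovery replicates, per-subgroup daily-intake samples — so every
downstream stage (validation, kinetics, deterministic and probabilistic
risk) is testable against the generating parameters.

The module-level ``STUDY_*`` constants encode the published grape study
conditions (calibration lines, half-life regimes, HR/STMR, subgroup
large portions and bodyweights, ADI/ARfD) used by the packaged example
pipeline.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from .deterministic import PopulationSubgroup, ResidueSummary, ToxicologyReference
from .dissipation import DissipationSeries

__all__ = [
    "SyntheticTrialConfig",
    "SyntheticPopulationConfig",
    "generate_decay_series",
    "generate_consumption_sample",
    "generate_recovery_table",
    "make_study_tables",
    "STUDY_SUBGROUPS",
    "STUDY_TOXICOLOGY",
    "STUDY_RESIDUE_SUMMARIES",
    "STUDY_CALIBRATION_LINES",
    "STUDY_HALF_LIVES",
]

LN2 = math.log(2)


def _lognormal_sigma_for_cv(cv: float) -> float:
    """Log-scale sigma giving a lognormal the requested coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


class SyntheticTrialConfig(BaseModel):
    """Ground truth for one simulated dissipation trial.

    c0_true (mg/kg) and k_true (1/day) parameterise the generating
    first-order curve; noise_cv is the coefficient of variation of the
    multiplicative lognormal measurement error (median 1); residues
    below loq are flagged censored but keep their latent value.
    """

    c0_true: float = Field(gt=0)
    k_true: float = Field(gt=0)
    sample_days: list[float]
    noise_cv: float = Field(default=0.0, ge=0)
    loq: float = Field(default=0.05, ge=0)
    seed: int = 0
    compound: str = "compound"
    site: str = "site"

    @field_validator("sample_days")
    @classmethod
    def _check_days(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("sample_days must be non-empty")
        if v[0] != 0:
            raise ValueError("sample_days must start at day 0")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("sample_days must be strictly increasing")
        return v


class SyntheticPopulationConfig(BaseModel):
    """Ground truth for one subgroup's consumption/bodyweight sample.

    Daily intake is lognormal(intake_mu, intake_sigma) in kg/day;
    bodyweight is normal with mean bw_mean and CV bw_cv, truncated at
    zero (bw_cv=0 gives the point bodyweight convention).
    """

    subgroup_name: str
    bw_mean: float = Field(gt=0)
    bw_cv: float = Field(default=0.0, ge=0)
    intake_mu: float
    intake_sigma: float = Field(ge=0)
    n_individuals: int = Field(ge=1)
    seed: int = 0


def generate_decay_series(config: SyntheticTrialConfig) -> DissipationSeries:
    """Simulate residues y(t) = C0*exp(-k t)*eps on the sampling days.

    eps is lognormal with median 1 and CV = noise_cv, so the noiseless
    curve is recovered exactly at noise_cv=0.  Values below the LOQ are
    flagged censored with the latent value retained.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.sample_days, dtype=float)
    values = config.c0_true * np.exp(-config.k_true * t)
    if config.noise_cv > 0:
        sigma = _lognormal_sigma_for_cv(config.noise_cv)
        values = values * rng.lognormal(mean=0.0, sigma=sigma, size=t.size)
    return DissipationSeries(
        compound=config.compound,
        site=config.site,
        days=t,
        residues=values,
        censored=values < config.loq,
        loq=config.loq,
    )


def generate_consumption_sample(config: SyntheticPopulationConfig) -> pd.DataFrame:
    """Simulate (intake kg/day, bodyweight kg) pairs for one subgroup.

    Returns a table with columns subgroup, intake_kg_per_day, bw_kg
    matching the consumption CSV schema.
    """
    rng = np.random.default_rng(config.seed)
    intake = rng.lognormal(config.intake_mu, config.intake_sigma, size=config.n_individuals)
    if config.bw_cv == 0:
        bw = np.full(config.n_individuals, config.bw_mean)
    else:
        sd = config.bw_cv * config.bw_mean
        a = (0.0 - config.bw_mean) / sd  # truncate at zero
        bw = stats.truncnorm.rvs(
            a, np.inf, loc=config.bw_mean, scale=sd, size=config.n_individuals, random_state=rng
        )
    return pd.DataFrame(
        {"subgroup": config.subgroup_name, "intake_kg_per_day": intake, "bw_kg": bw}
    )


def generate_recovery_table(
    true_level: float,
    recovery_mean: float,
    rsd: float,
    n_reps: int,
    seed: int = 0,
    compound: str = "compound",
) -> pd.DataFrame:
    """Simulate replicate measurements of a spiked blank sample.

    Measured values target mean true_level*recovery_mean with relative
    SD ~ rsd percent, using mean-1 lognormal multiplicative noise so
    concentrations stay strictly positive.  Columns match the recovery
    CSV schema: compound, spike_mg_per_kg, replicate, measured_mg_per_kg.
    """
    if true_level <= 0:
        raise ValueError(f"spike level must be positive, got {true_level}")
    if recovery_mean <= 0:
        raise ValueError(f"mean recovery must be positive, got {recovery_mean}")
    if rsd < 0:
        raise ValueError(f"RSD must be non-negative, got {rsd}")
    if n_reps < 2:
        raise ValueError(f"need at least 2 replicates, got {n_reps}")
    rng = np.random.default_rng(seed)
    target = true_level * recovery_mean
    if rsd == 0:
        measured = np.full(n_reps, target)
    else:
        sigma = _lognormal_sigma_for_cv(rsd / 100.0)
        # mean-1 lognormal: mu = -sigma^2/2
        measured = target * rng.lognormal(-0.5 * sigma * sigma, sigma, size=n_reps)
    return pd.DataFrame(
        {
            "compound": compound,
            "spike_mg_per_kg": true_level,
            "replicate": np.arange(1, n_reps + 1),
            "measured_mg_per_kg": measured,
        }
    )


# --------------------------------------------------------------------------
# Published grape-study conditions used by the packaged example pipeline.

#: (compound, medium) -> (slope, intercept) of the reported calibration lines.
STUDY_CALIBRATION_LINES: dict[tuple[str, str], tuple[float, float]] = {
    ("pyraclostrobin", "solvent"): (75.023, -0.1507),
    ("pyraclostrobin", "matrix"): (79.557, 0.8196),
    ("cyazofamid", "solvent"): (46.077, -0.5829),
    ("cyazofamid", "matrix"): (44.765, 0.4464),
    ("CCIM", "solvent"): (83.679, -1.0367),
    ("CCIM", "matrix"): (79.642, 0.9445),
}

#: Standard-series concentrations, mg/L.
STUDY_CALIBRATION_LEVELS = (0.05, 0.10, 0.20, 0.50, 1.0, 2.0, 5.0)

#: compound -> {site: (c0 mg/kg, half-life days)} spanning the reported regimes.
STUDY_HALF_LIVES: dict[str, dict[str, tuple[float, float]]] = {
    "pyraclostrobin": {"Guangxi": (0.65, 17.8), "Zhejiang": (0.52, 28.9)},
    "cyazofamid": {"Guangxi": (0.46, 4.3), "Zhejiang": (0.38, 7.8)},
    "CCIM": {"Guangxi": (0.32, 16.9)},
}

#: Dissipation sampling schedule, days after last application.
STUDY_DECAY_DAYS = [0.0, 3.0, 7.0, 14.0, 21.0, 28.0]

#: Subgroup large portions (kg/day) and bodyweights (kg); mean daily grape
#: intakes are survey-plausible values (the source microdata are not public).
STUDY_SUBGROUPS = (
    PopulationSubgroup(name="general", bw=53.23, lp=0.570, fi=0.048),
    PopulationSubgroup(name="children", bw=16.14, lp=0.366, fi=0.030),
    PopulationSubgroup(name="women_childbearing", bw=52.6, lp=0.297, fi=0.045),
)

STUDY_TOXICOLOGY = (
    ToxicologyReference(compound="pyraclostrobin", adi=0.03, arfd=0.05),
    ToxicologyReference(compound="cyazofamid", adi=0.2, arfd=0.2),
)

#: HR/STMR from the supervised trials; cyazofamid is the parent+CCIM total.
STUDY_RESIDUE_SUMMARIES = (
    ResidueSummary(compound="pyraclostrobin", hr=1.88, stmr=0.13),
    ResidueSummary(compound="cyazofamid", hr=0.78, stmr=0.11),
)

#: Spike levels and target recovery/RSD per compound for the recovery fixture.
_RECOVERY_DESIGN = {
    "pyraclostrobin": {"levels": (0.05, 0.50, 2.0), "recovery": 0.89, "rsd": 6.0},
    "cyazofamid": {"levels": (0.05, 0.50, 1.0), "recovery": 0.95, "rsd": 4.0},
    "CCIM": {"levels": (0.05, 0.50, 1.0), "recovery": 1.01, "rsd": 2.5},
}


def make_study_tables(seed: int = 0, n_consumers: int = 300, noise_cv: float = 0.1) -> dict[str, pd.DataFrame]:
    """Build the full set of study-shaped input tables.

    Returns a dict of DataFrames keyed by schema name: calibration,
    recovery, decay, residue (per-observation, LOQ-censored),
    residue_summary, subgroups, toxicology, consumption.  All randomness
    derives from ``seed``.
    """
    seed = int(seed) % (2**31)
    loq = 0.05

    cal_rows = []
    for (compound, medium), (slope, intercept) in sorted(STUDY_CALIBRATION_LINES.items()):
        for level in STUDY_CALIBRATION_LEVELS:
            cal_rows.append(
                {
                    "compound": compound,
                    "medium": medium,
                    "level_mg_per_L": level,
                    "response": slope * level + intercept,
                }
            )
    calibration = pd.DataFrame(cal_rows)

    rec_frames = []
    for i, (compound, design) in enumerate(sorted(_RECOVERY_DESIGN.items())):
        for j, level in enumerate(design["levels"]):
            rec_frames.append(
                generate_recovery_table(
                    true_level=level,
                    recovery_mean=design["recovery"],
                    rsd=design["rsd"],
                    n_reps=5,
                    seed=seed + 100 * i + j,
                    compound=compound,
                )
            )
    recovery = pd.concat(rec_frames, ignore_index=True)

    decay_frames = []
    offset = 0
    for compound, sites in sorted(STUDY_HALF_LIVES.items()):
        for site, (c0, t_half) in sorted(sites.items()):
            cfg = SyntheticTrialConfig(
                c0_true=c0,
                k_true=LN2 / t_half,
                sample_days=STUDY_DECAY_DAYS,
                noise_cv=noise_cv,
                loq=loq,
                seed=seed + 1000 + offset,
                compound=compound,
                site=site,
            )
            decay_frames.append(generate_decay_series(cfg).to_frame())
            offset += 1
    decay = pd.concat(decay_frames, ignore_index=True)

    # Per-observation final residues around each STMR for the lognormal fits;
    # 10 trial sites x 3 pre-harvest intervals.
    resid_rows = []
    for i, summary in enumerate(STUDY_RESIDUE_SUMMARIES):
        rng = np.random.default_rng(seed + 5000 + i)
        values = rng.lognormal(math.log(summary.stmr), 0.8, size=30)
        for v in values:
            resid_rows.append(
                {
                    "compound": summary.compound,
                    "residue_mg_per_kg": max(v, loq) if v < loq else v,
                    "censored": int(v < loq),
                }
            )
    residue = pd.DataFrame(resid_rows)

    cons_frames = []
    for i, sg in enumerate(STUDY_SUBGROUPS):
        cfg = SyntheticPopulationConfig(
            subgroup_name=sg.name,
            bw_mean=sg.bw,
            bw_cv=0.0,  # point bodyweight convention
            intake_mu=math.log(sg.fi),
            intake_sigma=0.5,
            n_individuals=n_consumers,
            seed=seed + 9000 + i,
        )
        cons_frames.append(generate_consumption_sample(cfg))
    consumption = pd.concat(cons_frames, ignore_index=True)

    subgroups = pd.DataFrame(
        [
            {
                "name": sg.name,
                "bw_kg": sg.bw,
                "lp_kg_per_day": sg.lp,
                "fi_kg_per_day": sg.fi,
                "v": sg.variability_factor,
            }
            for sg in STUDY_SUBGROUPS
        ]
    )
    toxicology = pd.DataFrame(
        [
            {"compound": t.compound, "adi_mg_per_kg_bw_day": t.adi, "arfd_mg_per_kg_bw": t.arfd}
            for t in STUDY_TOXICOLOGY
        ]
    )
    residue_summary = pd.DataFrame(
        [
            {"compound": r.compound, "hr_mg_per_kg": r.hr, "stmr_mg_per_kg": r.stmr}
            for r in STUDY_RESIDUE_SUMMARIES
        ]
    )

    return {
        "calibration": calibration,
        "recovery": recovery,
        "decay": decay,
        "residue": residue,
        "residue_summary": residue_summary,
        "subgroups": subgroups,
        "toxicology": toxicology,
        "consumption": consumption,
    }
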