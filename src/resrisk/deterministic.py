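"""Deterministic (point-estimate) dietary risk assessment.

Acute risk uses the estimated short-term intake

    NESTI = LP * HR * v / bw,

where LP is the large portion (97.5th-percentile single-day consumption,
kg/day), HR the highest residue from supervised trials (mg/kg), v the
unit-to-unit variability factor (3 for grapes) and bw the subgroup body
weight (kg).  Acute acceptability is %ARfD = 100 * NESTI / ARfD.

Chronic risk uses the estimated daily intake over registered foods

    EDI = sum_i STMR_i * F_i / bw,

with STMR the supervised-trials median residue and F_i the mean daily
consumption of food i; chronic acceptability is %ADI = 100 * EDI / ADI.
Either figure above 100% is deemed unacceptable.

Where a parent compound and its monitored metabolite are regulated
together, the total residue is parent + conversion_factor * metabolite;
the default factor of 1 sums concentrations directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .dissipation import CENSOR_POLICIES

__all__ = [
    "PopulationSubgroup",
    "ToxicologyReference",
    "ResidueSummary",
    "total_residue",
    "nesti",
    "percent_arfd",
    "edi",
    "risk_quotient",
    "is_acceptable",
    "risk_table",
]

#: Risk above this percentage of the reference dose is unacceptable.
ACCEPTABILITY_THRESHOLD = 100.0


@dataclass(frozen=True)
class PopulationSubgroup:
    """Consumption parameters for one named consumer group.

    lp is the large portion (kg/day), fi the mean daily intake of the
    commodity (kg/day), variability_factor the unit-to-unit residue
    variability multiplier v (default 3, the convention for grapes).
    """

    name: str
    bw: float
    lp: float
    fi: float
    variability_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError(f"bodyweight must be positive, got {self.bw}")
        if self.lp < 0:
            raise ValueError(f"large portion must be non-negative, got {self.lp}")
        if self.fi < 0:
            raise ValueError(f"mean intake must be non-negative, got {self.fi}")
        if self.variability_factor < 1:
            raise ValueError(
                f"variability factor must be >= 1, got {self.variability_factor}"
            )


@dataclass(frozen=True)
class ToxicologyReference:
    """Toxicological reference doses for one compound."""

    compound: str
    adi: float  # mg/kg bw/day
    arfd: float  # mg/kg bw

    def __post_init__(self) -> None:
        if self.adi <= 0:
            raise ValueError(f"ADI must be positive, got {self.adi}")
        if self.arfd <= 0:
            raise ValueError(f"ARfD must be positive, got {self.arfd}")


@dataclass(frozen=True)
class ResidueSummary:
    """Highest residue (HR) and supervised-trials median residue (STMR)."""

    compound: str
    hr: float  # mg/kg
    stmr: float  # mg/kg

    def __post_init__(self) -> None:
        if not (self.hr >= self.stmr >= 0):
            raise ValueError(
                f"need HR >= STMR >= 0, got HR={self.hr}, STMR={self.stmr}"
            )


def _substitute(value: float, censored: bool, policy: str, loq: float) -> float:
    if not censored:
        return value
    if policy == "drop":
        return 0.0
    if policy == "half_loq":
        return loq / 2.0
    return loq


def total_residue(
    parent: float,
    metabolite: float,
    conversion_factor: float = 1.0,
    *,
    parent_censored: bool = False,
    metabolite_censored: bool = False,
    loq: float = 0.0,
    censor_policy: str = "half_loq",
) -> float:
    """Total residue = parent + conversion_factor * metabolite, mg/kg.

    Censored (< LOQ) inputs are substituted per the active policy before
    summation.  The default conversion factor of 1 sums concentrations
    without molecular-weight adjustment.
    """
    if parent < 0 or metabolite < 0:
        raise ValueError("residue concentrations must be non-negative")
    if conversion_factor <= 0:
        raise ValueError(f"conversion factor must be positive, got {conversion_factor}")
    if censor_policy not in CENSOR_POLICIES:
        raise ValueError(f"unknown censor policy {censor_policy!r}")
    p = _substitute(parent, parent_censored, censor_policy, loq)
    m = _substitute(metabolite, metabolite_censored, censor_policy, loq)
    return p + conversion_factor * m


def nesti(subgroup: PopulationSubgroup, hr: float) -> float:
    """Estimated short-term intake LP*HR*v/bw, mg/kg bw."""
    if hr < 0:
        raise ValueError(f"highest residue must be non-negative, got {hr}")
    return subgroup.lp * hr * subgroup.variability_factor / subgroup.bw


def percent_arfd(nesti_value: float, arfd: float) -> float:
    """Acute risk as a percentage of the acute reference dose."""
    if arfd <= 0:
        raise ValueError(f"ARfD must be positive, got {arfd}")
    return 100.0 * nesti_value / arfd


def edi(stmr_by_food: Iterable[tuple[float, float]], bw: float) -> float:
    """Estimated daily intake sum(STMR_i * F_i) / bw, mg/kg bw/day.

    ``stmr_by_food`` iterates (STMR_i mg/kg, F_i kg/day) pairs over the
    registered foods; here a single commodity (grape) in practice.
    """
    if bw <= 0:
        raise ValueError(f"bodyweight must be positive, got {bw}")
    total = 0.0
    for stmr_i, fi in stmr_by_food:
        if stmr_i < 0 or fi < 0:
            raise ValueError("STMR and intake must be non-negative")
        total += stmr_i * fi
    return total / bw


def risk_quotient(edi_value: float, adi: float) -> float:
    """Chronic risk %ADI = 100 * EDI / ADI."""
    if adi <= 0:
        raise ValueError(f"ADI must be positive, got {adi}")
    return 100.0 * edi_value / adi


def is_acceptable(percent_of_reference: float) -> bool:
    """Risk is acceptable at or below 100% of the reference dose."""
    return percent_of_reference <= ACCEPTABILITY_THRESHOLD


def risk_table(
    residues: Sequence[ResidueSummary],
    subgroups: Sequence[PopulationSubgroup],
    toxicology: Sequence[ToxicologyReference],
) -> pd.DataFrame:
    """Acute and chronic point-estimate risks for every compound x subgroup.

    Columns: compound, subgroup, nesti, percent_arfd, edi, percent_adi,
    acceptable (1 when both figures are at or below 100%).
    """
    tox = {t.compound: t for t in toxicology}
    rows = []
    for summary in residues:
        if summary.compound not in tox:
            raise KeyError(f"no toxicology reference for compound {summary.compound!r}")
        ref = tox[summary.compound]
        for sg in subgroups:
            short = nesti(sg, summary.hr)
            acute = percent_arfd(short, ref.arfd)
            daily = edi([(summary.stmr, sg.fi)], sg.bw)
            chronic = risk_quotient(daily, ref.adi)
            rows.append(
                {
                    "compound": summary.compound,
                    "subgroup": sg.name,
                    "nesti": short,
                    "percent_arfd": acute,
                    "edi": daily,
                    "percent_adi": chronic,
                    "acceptable": int(is_acceptable(acute) and is_acceptable(chronic)),
                }
            )
    return pd.DataFrame(rows)
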