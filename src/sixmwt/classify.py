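"""Threshold rules: exercise-intolerance flags and categorical statuses.

All inequalities are applied exactly as defined clinically, with strict
boundaries where the definitions say "greater/less than":

* abnormal walk distance: measured < lower limit of normal (strict),
* chronotropic insufficiency: end-of-walk HR < 60 % of MPHR (strict),
* desaturation: SpO2 drop > 5 points (strict),
* high dyspnea: end-of-walk VAS > 5/10 (strict),
* sedentary: Voorrips total activity score < 9.42,
* smoker: ≥ 5 pack-years (inclusive),
* high parity: more than two children (women only),
* corpulence: BMI bins <18.5 / [18.5, 25) / [25, 30) / ≥30, half-open so
  the BMI axis is partitioned with no gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import ParticipantRecord
from .metrics import DerivedMetrics

__all__ = [
    "SignProfile",
    "CategoricalStatuses",
    "flag_abnormal_6mwd",
    "flag_chronotropic_insufficiency",
    "flag_desaturation",
    "flag_high_dyspnea",
    "flag_stopped",
    "classify_corpulence",
    "classify_sedentary",
    "classify_smoker",
    "classify_high_parity",
    "sign_profile",
    "categorical_statuses",
    "SEDENTARY_THRESHOLD",
    "SMOKER_PACK_YEARS",
]

SEDENTARY_THRESHOLD = 9.42
SMOKER_PACK_YEARS = 5.0
CHRONOTROPIC_PCT_MPHR = 60.0
DESATURATION_POINTS = 5.0
HIGH_DYSPNEA_VAS = 5.0
HIGH_PARITY = 2


def flag_abnormal_6mwd(measured: float, lln: float) -> bool:
    """True when the walked distance falls below the lower limit of normal."""
    return measured < lln


def flag_chronotropic_insufficiency(hr_end_pct_mphr: float) -> bool:
    """True when end-of-walk HR is below 60 % of the maximal predicted HR."""
    return hr_end_pct_mphr < CHRONOTROPIC_PCT_MPHR


def flag_desaturation(drop_points: float) -> bool:
    """True when SpO2 dropped by more than 5 points (rest − end)."""
    return drop_points > DESATURATION_POINTS


def flag_high_dyspnea(dyspnea_end: float) -> bool:
    """True when end-of-walk dyspnea exceeds 5 on the 0–10 VAS."""
    return dyspnea_end > HIGH_DYSPNEA_VAS


def flag_stopped(stops: int) -> bool:
    return stops > 0


def classify_corpulence(bmi: float) -> str:
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def classify_sedentary(voorrips_total: float) -> bool:
    """Sedentary below a total activity score of 9.42, active at or above."""
    if voorrips_total < 0:
        raise ValueError("activity score must be nonnegative")
    return voorrips_total < SEDENTARY_THRESHOLD


def classify_smoker(pack_years: float) -> bool:
    """Smoker at 5 pack-years or more (inclusive boundary)."""
    if pack_years < 0:
        raise ValueError("pack_years must be nonnegative")
    return pack_years >= SMOKER_PACK_YEARS


def classify_high_parity(parity: Optional[int], sex: int) -> Optional[bool]:
    """High parity = more than two children; not applicable (None) for men."""
    if sex == 0:
        return None
    if parity is None or parity < 0:
        raise ValueError("parity must be a nonnegative integer for women")
    return parity > HIGH_PARITY


@dataclass(frozen=True)
class SignProfile:
    """Boolean exercise-intolerance flags for one participant."""

    id: str
    abnormal_6mwd: bool
    stopped_during_walk: bool
    high_dyspnea_end: bool
    desaturation: bool
    chronotropic_insufficiency: bool


@dataclass(frozen=True)
class CategoricalStatuses:
    """Habit / anthropometric categories for one participant."""

    id: str
    corpulence: str
    sedentary: bool
    smoker: bool
    high_parity: Optional[bool]   # None = not applicable (men)


def sign_profile(record: ParticipantRecord,
                 metrics: DerivedMetrics) -> SignProfile:
    w = record.walk
    return SignProfile(
        id=record.id,
        abnormal_6mwd=flag_abnormal_6mwd(w.distance_m, metrics.lln_6mwd_m),
        stopped_during_walk=flag_stopped(w.stops),
        high_dyspnea_end=flag_high_dyspnea(w.dyspnea_end),
        desaturation=flag_desaturation(metrics.spo2_drop_points),
        chronotropic_insufficiency=flag_chronotropic_insufficiency(
            metrics.hr_end_pct_mphr),
    )


def categorical_statuses(record: ParticipantRecord) -> CategoricalStatuses:
    return CategoricalStatuses(
        id=record.id,
        corpulence=classify_corpulence(record.bmi),
        sedentary=classify_sedentary(record.voorrips_total),
        smoker=classify_smoker(record.pack_years),
        high_parity=classify_high_parity(record.parity, record.sex),
    )
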