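"""Per-participant derived walk-test metrics.

Percent of predicted distance, walk work (distance × body weight),
rest-to-end percentage deltas, SpO2 drop, heart rate as % of maximal
predicted, fitness-age gap (chronological − ECRMC age) and the
physiological cost index.

Sign conventions worth noting:

* ``spo2_drop_points`` is rest − end, so a positive drop means
  desaturation; the signed end − rest change is kept alongside it
  (``spo2_change_points``) for report parity.
* ``delta_age_years`` is chronological − fitness age, so negative values
  mean the walk test suggests an older functional age than the calendar
  (accelerated aging).
* No rest-to-end delta is defined for dyspnea: the resting score is 0, so
  the relative change is undefined; the absolute end value is reported
  instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import ParticipantRecord
from .reference import (CoefficientSet, NORTH_AFRICAN, ecrmc_age,
                        ecrmc_age_implausible, lln_6mwd, mphr,
                        predicted_6mwd)

__all__ = [
    "DerivedMetrics",
    "percent_predicted",
    "walk_work",
    "delta_percent",
    "spo2_drop",
    "hr_pct_mphr",
    "delta_age",
    "physiological_cost_index",
    "compute_metrics",
    "PCI_HEALTHY_RANGE",
]

#: Typical physiological cost index of healthy adults, beats per metre.
PCI_HEALTHY_RANGE = (0.23, 0.42)


def percent_predicted(measured: float, predicted: float) -> float:
    """Measured 6MWD as a percentage of the predicted distance."""
    if predicted <= 0:
        raise ValueError("predicted distance must be positive")
    return 100.0 * measured / predicted


def walk_work(distance: float, weight: float) -> float:
    """Six-minute walk work: distance × body weight (m·kg)."""
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    if weight <= 0:
        raise ValueError("weight must be positive")
    return distance * weight


def delta_percent(end: float, rest: float) -> float:
    """Relative rest-to-end change, 100·(end − rest)/rest."""
    if rest == 0:
        raise ZeroDivisionError(
            "relative change undefined when the resting value is 0")
    return 100.0 * (end - rest) / rest


def spo2_drop(rest: float, end: float) -> float:
    """SpO2 drop in percentage points; positive = desaturation."""
    return rest - end


def hr_pct_mphr(hr: float, age: float) -> float:
    """Heart rate as a percentage of the maximal predicted heart rate."""
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    maximal = mphr(age)
    if maximal <= 0:
        raise ValueError("maximal predicted heart rate is nonpositive")
    return 100.0 * hr / maximal


def delta_age(chronological: float, ecrmc: float) -> float:
    """Chronological minus fitness age; negative = accelerated aging."""
    return chronological - ecrmc


def physiological_cost_index(hr_end: float, hr_rest: float,
                             distance: float) -> float:
    """Extra heart beats per metre walked: (HRend − HRrest) / speed.

    Speed is in metres per minute (distance / 6), so the index is in beats
    per metre. Healthy adults typically fall in 0.23–0.42.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    return (hr_end - hr_rest) / (distance / 6.0)


@dataclass(frozen=True)
class DerivedMetrics:
    """Every computed per-participant quantity, ready for the tidy export."""

    id: str
    predicted_6mwd_m: float
    lln_6mwd_m: float
    equation_branch: str
    pct_predicted_6mwd: float
    walk_work_m_kg: float
    hr_rest_pct_mphr: float
    hr_end_pct_mphr: float
    delta_hr_pct: float
    delta_sbp_pct: float
    delta_dbp_pct: float
    delta_spo2_pct: float
    spo2_drop_points: float          # rest − end; positive = desaturation
    spo2_change_points: float        # end − rest (signed, report parity)
    ecrmc_age_years: float
    ecrmc_age_implausible: bool
    delta_age_years: float
    pci_beats_per_m: Optional[float]


def compute_metrics(record: ParticipantRecord,
                    coefficients: CoefficientSet = NORTH_AFRICAN,
                    include_pci: bool = True) -> DerivedMetrics:
    """Compute the full derived-metrics row for one participant."""
    w = record.walk
    predicted = predicted_6mwd(record.sex, record.age, record.weight,
                               record.height, record.bmi, coefficients)
    lln = lln_6mwd(predicted, record.age, coefficients)
    fitness_age = ecrmc_age(record.sex, record.age, record.weight,
                            record.height, w.distance_m, coefficients)
    return DerivedMetrics(
        id=record.id,
        predicted_6mwd_m=predicted,
        lln_6mwd_m=lln,
        equation_branch="under40" if record.age < 40.0 else "forty_plus",
        pct_predicted_6mwd=percent_predicted(w.distance_m, predicted),
        walk_work_m_kg=walk_work(w.distance_m, record.weight),
        hr_rest_pct_mphr=hr_pct_mphr(w.hr_rest, record.age),
        hr_end_pct_mphr=hr_pct_mphr(w.hr_end, record.age),
        delta_hr_pct=delta_percent(w.hr_end, w.hr_rest),
        delta_sbp_pct=delta_percent(w.sbp_end, w.sbp_rest),
        delta_dbp_pct=delta_percent(w.dbp_end, w.dbp_rest),
        delta_spo2_pct=delta_percent(w.spo2_end, w.spo2_rest),
        spo2_drop_points=spo2_drop(w.spo2_rest, w.spo2_end),
        spo2_change_points=w.spo2_end - w.spo2_rest,
        ecrmc_age_years=fitness_age,
        ecrmc_age_implausible=ecrmc_age_implausible(fitness_age),
        delta_age_years=delta_age(record.age, fitness_age),
        pci_beats_per_m=(physiological_cost_index(
            w.hr_end, w.hr_rest, w.distance_m) if include_pci else None),
    )
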