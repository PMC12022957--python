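"""Reference equations for the six-minute walk test (North African adults).

Two age branches (< 40 years and ≥ 40 years) for each of:

* predicted six-minute walk distance (6MWD, metres),
* its lower limit of normal (LLN = predicted − fixed offset),
* the estimated cardiorespiratory-and-muscular-chain age ("fitness age",
  ECRMC, years),

plus the age-based maximal predicted heart rate, MPHR = 208 − 0.7·age.

Sex is encoded 0 = man, 1 = woman throughout (the equations' convention).
The two source equation sets use slightly different wording for the branch
point ("older than 40" vs "aged 40 and more"); this package assigns age
exactly 40 to the 40-plus branch for every equation so that prediction and
fitness age always come from the same branch for a given participant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Union

__all__ = [
    "CoefficientSet",
    "ReferencePrediction",
    "NORTH_AFRICAN",
    "get_coefficients",
    "register_coefficients",
    "load_coefficients",
    "dump_coefficients",
    "predicted_6mwd",
    "lln_6mwd",
    "ecrmc_age",
    "mphr",
    "ECRMC_PLAUSIBLE_RANGE",
]

#: Fitness ages outside this band are returned unchanged but flagged.
ECRMC_PLAUSIBLE_RANGE = (0.0, 120.0)


@dataclass(frozen=True)
class CoefficientSet:
    """Named coefficients for one population's reference equations.

    Each equation is a linear form; coefficient keys name the regressor
    they multiply (``intercept``, ``sex``, ``age``, ``weight``, ``height``,
    ``bmi``, ``distance``). Missing keys are treated as zero only in the
    sense that the canonical sets simply omit regressors an equation does
    not use; user-supplied sets must name every coefficient they need.
    """

    name: str
    sixmwd_under40: dict[str, float]
    sixmwd_40plus: dict[str, float]
    ecrmc_under40: dict[str, float]
    ecrmc_40plus: dict[str, float]
    lln_offset_under40: float
    lln_offset_40plus: float
    mphr_intercept: float = 208.0
    mphr_age_slope: float = 0.7

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        return cls(**d)


#: Default coefficient set (North African adult reference values).
NORTH_AFRICAN = CoefficientSet(
    name="north_african",
    sixmwd_under40={"intercept": 800.05, "sex": -64.71, "bmi": -10.23,
                    "age": -1.63, "weight": 2.05},
    sixmwd_40plus={"intercept": 720.50, "sex": -160.27, "age": -5.14,
                   "weight": -2.23, "height": 271.98},
    ecrmc_under40={"intercept": 184.25, "distance": -0.36, "height": 44.39,
                   "sex": -13.87},
    ecrmc_40plus={"intercept": 140.17, "distance": -0.19, "sex": -31.18,
                  "weight": -0.43, "height": 52.91},
    lln_offset_under40=74.31,
    lln_offset_40plus=89.0,
)

_REGISTRY: dict[str, CoefficientSet] = {NORTH_AFRICAN.name: NORTH_AFRICAN}


def get_coefficients(name: str) -> CoefficientSet:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no coefficient set named {name!r}; "
            f"known: {sorted(_REGISTRY)}") from None


def register_coefficients(cs: CoefficientSet) -> None:
    """Add a population's coefficient set to the in-process registry."""
    _REGISTRY[cs.name] = cs


def load_coefficients(path) -> CoefficientSet:
    """Load a coefficient set from a JSON config file and register it."""
    with open(path, encoding="utf-8") as fh:
        cs = CoefficientSet.from_dict(json.load(fh))
    register_coefficients(cs)
    return cs


def dump_coefficients(cs: CoefficientSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cs.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass(frozen=True)
class ReferencePrediction:
    """Predicted 6MWD and its lower limit of normal for one participant."""

    predicted_6mwd_m: float
    lln_6mwd_m: float
    equation_branch: str   # "under40" | "forty_plus"


def _branch(age: float) -> str:
    return "under40" if age < 40.0 else "forty_plus"


def _evaluate(coeffs: dict[str, float], **regressors: float) -> float:
    total = coeffs["intercept"]
    for key, beta in coeffs.items():
        if key != "intercept":
            total += beta * regressors[key]
    return total


def predicted_6mwd(sex: int, age: float, weight: float, height: float,
                   bmi: Union[float, None] = None,
                   coefficients: CoefficientSet = NORTH_AFRICAN) -> float:
    """Predicted six-minute walk distance in metres.

    Under 40 the equation uses sex, BMI, age and weight; from 40 on it uses
    sex, age, weight and height (metres). ``bmi`` defaults to
    weight/height².
    """
    if weight <= 0 or height <= 0 or age <= 0:
        raise ValueError("anthropometrics must be positive")
    if bmi is None:
        bmi = weight / height**2
    elif bmi <= 0:
        raise ValueError("bmi must be positive")
    if age < 40.0:
        return _evaluate(coefficients.sixmwd_under40,
                         sex=sex, bmi=bmi, age=age, weight=weight)
    return _evaluate(coefficients.sixmwd_40plus,
                     sex=sex, age=age, weight=weight, height=height)


def lln_6mwd(predicted: float, age: float,
             coefficients: CoefficientSet = NORTH_AFRICAN) -> float:
    """Lower limit of normal: predicted 6MWD minus the branch offset."""
    if predicted <= 0:
        raise ValueError("predicted distance must be positive")
    offset = (coefficients.lln_offset_under40 if age < 40.0
              else coefficients.lln_offset_40plus)
    return predicted - offset


def reference_prediction(sex: int, age: float, weight: float, height: float,
                         bmi: Union[float, None] = None,
                         coefficients: CoefficientSet = NORTH_AFRICAN,
                         ) -> ReferencePrediction:
    pred = predicted_6mwd(sex, age, weight, height, bmi, coefficients)
    return ReferencePrediction(
        predicted_6mwd_m=pred,
        lln_6mwd_m=lln_6mwd(pred, age, coefficients),
        equation_branch=_branch(age),
    )


def ecrmc_age(sex: int, age: float, weight: float, height: float,
              measured_6mwd: float,
              coefficients: CoefficientSet = NORTH_AFRICAN) -> float:
    """Estimated cardiorespiratory-and-muscular-chain ("fitness") age.

    May fall outside plausible human ages for extreme walk distances; the
    value is returned as-is (callers flag it against
    :data:`ECRMC_PLAUSIBLE_RANGE`).
    """
    if measured_6mwd <= 0:
        raise ValueError("measured distance must be positive")
    if age < 40.0:
        return _evaluate(coefficients.ecrmc_under40,
                         distance=measured_6mwd, height=height, sex=sex)
    return _evaluate(coefficients.ecrmc_40plus,
                     distance=measured_6mwd, sex=sex, weight=weight,
                     height=height)


def ecrmc_age_implausible(value: float) -> bool:
    lo, hi = ECRMC_PLAUSIBLE_RANGE
    return not (lo <= value <= hi)


def mphr(age: float, coefficients: CoefficientSet = NORTH_AFRICAN) -> float:
    """Maximal predicted heart rate in bpm: 208 − 0.7·age."""
    if age < 0:
        raise ValueError("age must be nonnegative")
    return coefficients.mphr_intercept - coefficients.mphr_age_slope * age
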