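"""Seeded synthetic case-control cohort generator.

Draws per-group cohorts whose marginal moments and trait prevalences match
a :class:`CohortSpec`; the calibration preset carries the moments of a
chronic-hepatitis-B case-control walk-test study (26 cases / 28 controls).

Design:

* continuous variables are truncated normals at the spec'd mean/SD within
  stated physiologic bounds;
* walk distance and end-of-walk heart rate are drawn jointly through a
  Gaussian copula with a configurable rank correlation (the chronotropic
  link); every other variable is independent within group — a deliberate
  simplification (see the methods note);
* binary traits are Bernoulli; the number of women per group is fixed at
  round(n · fraction) so the preset reproduces the study's sex split
  exactly;
* one master seed; every (group, variable) pair gets its own deterministic
  substream, so adding a variable never perturbs previously generated
  columns, and a fixed spec + seed reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import stats as sps

from .cohort import Cohort, ParticipantRecord, WalkTestMeasurements
from .stats import mann_whitney_u

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "SpecError",
    "generate_cohort",
    "calibration_preset",
    "null_preset",
    "design_point_preset",
    "effect_recovery_experiment",
    "PowerReport",
]


class SpecError(ValueError):
    """The generator spec is internally inconsistent."""


# Physiologic truncation bounds (per variable).
BOUNDS = {
    "height": (1.40, 2.05),
    "weight": (40.0, 160.0),
    "distance": (200.0, 900.0),
    "hr_rest": (40.0, 120.0),
    "hr_end": (60.0, 220.0),
    "spo2_rest": (85.0, 100.0),
    "spo2_end": (85.0, 100.0),
    "sbp_rest": (80.0, 220.0),
    "sbp_end": (80.0, 240.0),
    "dbp_rest": (40.0, 130.0),
    "dbp_end": (40.0, 140.0),
    "dyspnea_end": (0.0, 10.0),
    "voorrips_total": (0.0, 30.0),
    "parity": (0.0, 8.0),
}

# Fixed split of the total physical-activity score into its three
# sub-scores (fractions follow the case group's component means).
VOORRIPS_SPLIT = {"daily": 0.55, "sport": 0.22, "leisure": 0.23}

# Substream index per variable; append-only so existing columns are stable.
_STREAMS = {name: i for i, name in enumerate([
    "sex_order", "age", "height", "weight", "distance_hr_end", "hr_rest",
    "spo2_rest", "spo2_end", "sbp_rest", "sbp_end", "dbp_rest", "dbp_end",
    "dyspnea_end", "voorrips_total", "parity", "smoker", "pack_years",
    "schooling", "ses",
])}


@dataclass(frozen=True)
class GroupSpec:
    """Marginal moments and trait prevalences for one group."""

    n: int
    sex_fraction_women: float
    age: tuple[float, float, float, float]      # mean, sd, min, max
    height: tuple[float, float]                 # metres
    weight: tuple[float, float]                 # kg
    distance: tuple[float, float]               # m
    hr_rest: tuple[float, float]                # bpm
    hr_end: tuple[float, float]
    spo2_rest: tuple[float, float]              # %
    spo2_end: tuple[float, float]
    sbp_rest: tuple[float, float]               # mmHg
    sbp_end: tuple[float, float]
    dbp_rest: tuple[float, float]
    dbp_end: tuple[float, float]
    dyspnea_end: tuple[float, float]            # VAS 0-10
    voorrips_total: tuple[float, float]
    parity: tuple[float, float]                 # women only, rounded to int
    smoker_prob: float
    low_schooling_prob: float
    unfavorable_ses_prob: float
    correlation_distance_hr_end: float = 0.4

    def validate(self) -> None:
        if self.n < 1:
            raise SpecError("group size must be ≥ 1")
        for pname in ("sex_fraction_women", "smoker_prob",
                      "low_schooling_prob", "unfavorable_ses_prob"):
            v = getattr(self, pname)
            if not (0.0 <= v <= 1.0):
                raise SpecError(f"{pname} must be in [0, 1]")
        if not (-1.0 < self.correlation_distance_hr_end < 1.0):
            raise SpecError("correlation must be in (-1, 1)")
        mean, sd, lo, hi = self.age
        if sd < 0:
            raise SpecError("age sd must be nonnegative")
        if not (lo < hi):
            raise SpecError("age truncation bounds must satisfy min < max")
        if not (lo <= mean <= hi):
            raise SpecError("age mean outside truncation bounds")
        for vname, bounds_key in (
                ("height", "height"), ("weight", "weight"),
                ("distance", "distance"), ("hr_rest", "hr_rest"),
                ("hr_end", "hr_end"), ("spo2_rest", "spo2_rest"),
                ("spo2_end", "spo2_end"), ("sbp_rest", "sbp_rest"),
                ("sbp_end", "sbp_end"), ("dbp_rest", "dbp_rest"),
                ("dbp_end", "dbp_end"), ("dyspnea_end", "dyspnea_end"),
                ("voorrips_total", "voorrips_total"), ("parity", "parity")):
            m, s = getattr(self, vname)
            if s < 0:
                raise SpecError(f"{vname} sd must be nonnegative")
            lo, hi = BOUNDS[bounds_key]
            if not (lo <= m <= hi):
                raise SpecError(f"{vname} mean {m} outside truncation "
                                f"bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class CohortSpec:
    """Full two-group generator specification."""

    case: GroupSpec
    control: GroupSpec
    seed: int = 0

    def validate(self) -> None:
        self.case.validate()
        self.control.validate()

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)

        def _group(g: dict) -> GroupSpec:
            g = dict(g)
            for k, v in g.items():
                if isinstance(v, list):
                    g[k] = tuple(v)
            return GroupSpec(**g)

        return cls(case=_group(d["case"]), control=_group(d["control"]),
                   seed=int(d["seed"]))


def _rng(seed: int, group_idx: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(group_idx, _STREAMS[stream])))


def _truncnorm(rng: np.random.Generator, n: int, mean: float, sd: float,
               lo: float, hi: float) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                             random_state=rng)


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float,
                   lo: float, hi: float) -> np.ndarray:
    if sd == 0.0:
        return np.full(u.shape, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _generate_group(spec: GroupSpec, group: str, group_idx: int,
                    seed: int) -> list[ParticipantRecord]:
    n = spec.n

    # Sex: exact count of women, order shuffled deterministically.
    n_women = int(round(n * spec.sex_fraction_women))
    sex = np.array([1] * n_women + [0] * (n - n_women))
    _rng(seed, group_idx, "sex_order").shuffle(sex)

    mean, sd, lo, hi = spec.age
    age = _truncnorm(_rng(seed, group_idx, "age"), n, mean, sd, lo, hi)
    height = _truncnorm(_rng(seed, group_idx, "height"), n,
                        *spec.height, *BOUNDS["height"])
    weight = _truncnorm(_rng(seed, group_idx, "weight"), n,
                        *spec.weight, *BOUNDS["weight"])

    # Distance and end HR through a Gaussian copula.
    rho = spec.correlation_distance_hr_end
    z = _rng(seed, group_idx, "distance_hr_end").standard_normal((n, 2))
    z[:, 1] = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
    u = sps.norm.cdf(z)
    distance = _truncnorm_ppf(u[:, 0], *spec.distance, *BOUNDS["distance"])
    hr_end = _truncnorm_ppf(u[:, 1], *spec.hr_end, *BOUNDS["hr_end"])

    simple = {}
    for vname in ("hr_rest", "spo2_rest", "spo2_end", "sbp_rest", "sbp_end",
                  "dbp_rest", "dbp_end", "dyspnea_end", "voorrips_total"):
        simple[vname] = _truncnorm(_rng(seed, group_idx, vname), n,
                                   *getattr(spec, vname), *BOUNDS[vname])

    parity_draw = np.rint(_truncnorm(_rng(seed, group_idx, "parity"), n,
                                     *spec.parity, *BOUNDS["parity"]))

    smoker = (_rng(seed, group_idx, "smoker").random(n) < spec.smoker_prob)
    pk_rng = _rng(seed, group_idx, "pack_years")
    pack_years = np.where(
        smoker,
        _truncnorm(pk_rng, n, 15.0, 8.0, 5.0, 60.0),
        _truncnorm(pk_rng, n, 1.0, 1.5, 0.0, 4.9),
    )
    low_school = (_rng(seed, group_idx, "schooling").random(n)
                  < spec.low_schooling_prob)
    unfav_ses = (_rng(seed, group_idx, "ses").random(n)
                 < spec.unfavorable_ses_prob)

    records = []
    for i in range(n):
        walk = WalkTestMeasurements(
            distance_m=float(distance[i]), stops=0,
            hr_rest=float(simple["hr_rest"][i]), hr_end=float(hr_end[i]),
            spo2_rest=float(simple["spo2_rest"][i]),
            spo2_end=float(simple["spo2_end"][i]),
            sbp_rest=float(simple["sbp_rest"][i]),
            sbp_end=float(simple["sbp_end"][i]),
            dbp_rest=float(simple["dbp_rest"][i]),
            dbp_end=float(simple["dbp_end"][i]),
            dyspnea_rest=0.0,   # resting breathlessness is 0 on the VAS
            dyspnea_end=float(simple["dyspnea_end"][i]),
        )
        total = float(simple["voorrips_total"][i])
        records.append(ParticipantRecord(
            id=f"{group}-{i + 1:02d}",
            group=group,
            sex=int(sex[i]),
            age=float(age[i]),
            height=float(height[i]),
            weight=float(weight[i]),
            bmi=float(weight[i] / height[i]**2),
            parity=int(parity_draw[i]) if sex[i] == 1 else None,
            pack_years=float(pack_years[i]),
            voorrips_daily=total * VOORRIPS_SPLIT["daily"],
            voorrips_sport=total * VOORRIPS_SPLIT["sport"],
            voorrips_leisure=total * VOORRIPS_SPLIT["leisure"],
            schooling_level="low" if low_school[i] else "high",
            socioeconomic_level="unfavorable" if unfav_ses[i] else "favorable",
            walk=walk,
        ))
    return records


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a deterministic two-group cohort from a spec.

    The same spec and seed always produce the identical cohort.
    """
    spec.validate()
    cohort = Cohort(provenance=f"synthetic (seed {spec.seed})")
    cohort.records.extend(
        _generate_group(spec.case, "case", 0, spec.seed))
    cohort.records.extend(
        _generate_group(spec.control, "control", 1, spec.seed))
    return cohort


# ---------------------------------------------------------------------------
# Presets

def calibration_preset(seed: int = 0) -> CohortSpec:
    """Spec emulating the chronic-hepatitis-B walk-test study.

    26 cases (11 women) vs 28 controls (13 women), with each group's
    published means/SDs for anthropometrics, walk distance, vitals,
    activity score, and trait prevalences. The distance–HRend rank
    correlation of 0.4 is a plausibility choice, not a published value.
    """
    case = GroupSpec(
        n=26, sex_fraction_women=11 / 26,
        age=(42.0, 6.0, 25.0, 60.0),
        height=(1.71, 0.10), weight=(82.0, 18.0),
        distance=(641.0, 57.0),
        hr_rest=(67.0, 8.0), hr_end=(127.0, 27.0),
        spo2_rest=(97.9, 0.9), spo2_end=(98.4, 0.9),
        sbp_rest=(119.0, 13.0), sbp_end=(148.0, 21.0),
        dbp_rest=(77.0, 11.0), dbp_end=(79.0, 9.0),
        dyspnea_end=(1.6, 1.2),
        voorrips_total=(3.24, 3.18),
        parity=(2.0, 1.0),
        smoker_prob=10 / 26,
        low_schooling_prob=8 / 26,
        unfavorable_ses_prob=9 / 26,
    )
    control = GroupSpec(
        n=28, sex_fraction_women=13 / 28,
        age=(37.0, 7.0, 20.0, 60.0),
        height=(1.73, 0.10), weight=(82.0, 14.0),
        distance=(702.0, 60.0),
        hr_rest=(68.0, 11.0), hr_end=(153.0, 22.0),
        spo2_rest=(98.3, 0.8), spo2_end=(97.9, 1.2),
        sbp_rest=(114.0, 12.0), sbp_end=(147.0, 20.0),
        dbp_rest=(73.0, 11.0), dbp_end=(77.0, 13.0),
        dyspnea_end=(1.1, 0.8),
        voorrips_total=(4.27, 4.45),
        parity=(1.0, 1.0),
        smoker_prob=5 / 28,
        low_schooling_prob=1 / 28,
        unfavorable_ses_prob=3 / 28,
    )
    return CohortSpec(case=case, control=control, seed=seed)


def null_preset(seed: int = 0) -> CohortSpec:
    """Both groups drawn from the control distribution (26 vs 28)."""
    base = calibration_preset(seed)
    return CohortSpec(case=replace(base.control, n=26,
                                   sex_fraction_women=11 / 26),
                      control=base.control, seed=seed)


def design_point_preset(seed: int = 0) -> CohortSpec:
    """The sample-size design point: distance 390 vs 421 m, SD 50, 27/27."""
    base = calibration_preset(seed)
    case = replace(base.case, n=27, distance=(390.0, 50.0))
    control = replace(base.control, n=27, distance=(421.0, 50.0))
    return CohortSpec(case=case, control=control, seed=seed)


# ---------------------------------------------------------------------------
# Effect-recovery / power experiment

@dataclass(frozen=True)
class PowerReport:
    replicates: int
    rejections: int
    power: float
    ci95_low: float
    ci95_high: float
    alpha: float


def effect_recovery_experiment(spec: CohortSpec, replicates: int,
                               seed: int, alpha: float = 0.05) -> PowerReport:
    """Empirical rejection rate of the distance comparison.

    For each replicate a fresh cohort is generated from ``spec`` (with a
    deterministic per-replicate seed derived from ``seed``) and the
    two-sided Mann-Whitney test on walk distance is run at level
    ``alpha``. Reports the rejection fraction with a Wilson 95 % CI.
    Under a null spec this measures type-I error; at an effect spec,
    power.
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates)
    rejections = 0
    for rep in range(replicates):
        rep_seed = int(child_seeds[rep]) % (2**31 - 1)
        cohort = generate_cohort(replace(spec, seed=rep_seed))
        x = [r.walk.distance_m for r in cohort.group("case")]
        y = [r.walk.distance_m for r in cohort.group("control")]
        _, p = mann_whitney_u(x, y)
        if p < alpha:
            rejections += 1
    power = rejections / replicates
    # Wilson score interval
    z = 1.959963984540054
    denom = 1 + z**2 / replicates
    centre = (power + z**2 / (2 * replicates)) / denom
    half = z * math.sqrt(power * (1 - power) / replicates
                         + z**2 / (4 * replicates**2)) / denom
    return PowerReport(replicates=replicates, rejections=rejections,
                       power=power, ci95_low=max(0.0, centre - half),
                       ci95_high=min(1.0, centre + half), alpha=alpha)
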