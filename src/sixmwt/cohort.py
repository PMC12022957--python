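"""Cohort data model: participant records, CSV schema, validation.

One row per participant. A row either validates into a
:class:`ParticipantRecord` or lands in the cohort's exclusion log with a
machine-readable reason — rows are never silently dropped.

CSV dialect is fixed: UTF-8, comma-separated, ``.`` decimal mark, empty
cell = missing. Height is stored internally in metres; the reader accepts
centimetres (any height value > 3 is interpreted as cm and divided by 100).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "WalkTestMeasurements",
    "ParticipantRecord",
    "Cohort",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

#: Canonical column order of the cohort CSV.
COHORT_COLUMNS = [
    "id", "group", "sex", "age", "height", "weight", "bmi", "parity",
    "pack_years", "voorrips_daily", "voorrips_sport", "voorrips_leisure",
    "schooling_level", "socioeconomic_level",
    "distance_m", "stops", "hr_rest", "hr_end",
    "spo2_rest", "spo2_end", "sbp_rest", "sbp_end", "dbp_rest", "dbp_end",
    "dyspnea_rest", "dyspnea_end",
]

# Accepted spellings for the 0 = man / 1 = woman encoding used by the
# reference equations.
_SEX_ALIASES = {
    "m": 0, "man": 0, "0": 0,
    "f": 1, "woman": 1, "1": 1,
}

_GROUPS = ("case", "control")
_SCHOOLING = ("low", "high")
_SES = ("unfavorable", "favorable")

# Physiologic plausibility ranges enforced at read time.
AGE_RANGE = (18.0, 90.0)
HEIGHT_RANGE = (1.2, 2.2)   # metres, after cm normalization
WEIGHT_RANGE = (30.0, 200.0)
SPO2_RANGE = (50.0, 100.0)
DYSPNEA_RANGE = (0.0, 10.0)
BMI_TOLERANCE = 0.5         # kg/m² agreement between stated and recomputed BMI


class SchemaError(ValueError):
    """The CSV header does not match the documented cohort schema."""


@dataclass(frozen=True)
class WalkTestMeasurements:
    """Vitals and performance of one six-minute walk test.

    Heart rate, SpO2, blood pressure and dyspnea are paired rest/end
    measurements; ``distance_m`` is the distance covered in six minutes and
    ``stops`` the number of times the participant stopped walking.
    """

    distance_m: float
    stops: int
    hr_rest: float
    hr_end: float
    spo2_rest: float
    spo2_end: float
    sbp_rest: float
    sbp_end: float
    dbp_rest: float
    dbp_end: float
    dyspnea_rest: float
    dyspnea_end: float


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: demographics, habits and walk-test measurements.

    ``sex`` uses the reference equations' convention: 0 = man, 1 = woman.
    ``parity`` is recorded for women only and is ``None`` for men.
    """

    id: str
    group: str                 # "case" | "control"
    sex: int                   # 0 = man, 1 = woman
    age: float                 # years
    height: float              # metres
    weight: float              # kg
    bmi: float                 # kg/m²
    parity: Optional[int]
    pack_years: float
    voorrips_daily: float
    voorrips_sport: float
    voorrips_leisure: float
    schooling_level: str       # "low" | "high"
    socioeconomic_level: str   # "unfavorable" | "favorable"
    walk: WalkTestMeasurements

    @property
    def voorrips_total(self) -> float:
        return self.voorrips_daily + self.voorrips_sport + self.voorrips_leisure


@dataclass
class Cohort:
    """Validated participant records plus the log of excluded rows."""

    records: list[ParticipantRecord] = field(default_factory=list)
    provenance: str = ""
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def group(self, name: str) -> list[ParticipantRecord]:
        return [r for r in self.records if r.group == name]

    @property
    def n_case(self) -> int:
        return len(self.group("case"))

    @property
    def n_control(self) -> int:
        return len(self.group("control"))


# ---------------------------------------------------------------------------
# Row validation

def _parse_float(raw: str, name: str, errors: list[str]) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        errors.append(f"missing field {name}")
        return None
    try:
        value = float(raw)
    except ValueError:
        errors.append(f"{name} not numeric: {raw!r}")
        return None
    if not math.isfinite(value):
        errors.append(f"{name} not finite")
        return None
    return value


def _check_range(value: Optional[float], name: str, lo: float, hi: float,
                 errors: list[str]) -> Optional[float]:
    if value is not None and not (lo <= value <= hi):
        errors.append(f"{name} out of [{lo:g},{hi:g}]")
        return None
    return value


def _validate_row(row: Mapping[str, str]) -> ParticipantRecord:
    """Validate one raw CSV row; raise ``ValueError`` listing every defect."""
    errors: list[str] = []

    rid = row.get("id", "").strip()
    if not rid:
        errors.append("missing field id")

    group = row.get("group", "").strip().lower()
    if group not in _GROUPS:
        errors.append(f"group not in {_GROUPS}: {row.get('group')!r}")

    sex_raw = row.get("sex", "").strip().lower()
    sex = _SEX_ALIASES.get(sex_raw)
    if sex is None:
        errors.append(f"sex alias not recognized: {row.get('sex')!r}")

    age = _check_range(_parse_float(row.get("age", ""), "age", errors),
                       "age", *AGE_RANGE, errors)

    height = _parse_float(row.get("height", ""), "height", errors)
    if height is not None and height > 3.0:   # centimetres → metres
        height = height / 100.0
    height = _check_range(height, "height", *HEIGHT_RANGE, errors)

    weight = _check_range(_parse_float(row.get("weight", ""), "weight", errors),
                          "weight", *WEIGHT_RANGE, errors)

    bmi_raw = row.get("bmi", "").strip()
    bmi: Optional[float] = None
    if height is not None and weight is not None:
        computed_bmi = weight / height**2
        if bmi_raw == "":
            bmi = computed_bmi
        else:
            stated = _parse_float(bmi_raw, "bmi", errors)
            if stated is not None:
                if abs(stated - computed_bmi) > BMI_TOLERANCE:
                    errors.append(
                        f"bmi inconsistent with weight/height^2 by "
                        f"{abs(stated - computed_bmi):.2f} kg/m2")
                else:
                    bmi = stated

    parity_raw = row.get("parity", "").strip()
    parity: Optional[int] = None
    if sex == 1:
        if parity_raw == "":
            errors.append("missing field parity")
        else:
            p = _parse_float(parity_raw, "parity", errors)
            if p is not None:
                if p < 0 or p != int(p):
                    errors.append("parity not a nonnegative integer")
                else:
                    parity = int(p)
    elif sex == 0 and parity_raw != "":
        errors.append("parity present for man")

    pack_years = _parse_float(row.get("pack_years", ""), "pack_years", errors)
    if pack_years is not None and pack_years < 0:
        errors.append("pack_years negative")

    voorrips = {}
    for part in ("daily", "sport", "leisure"):
        v = _parse_float(row.get(f"voorrips_{part}", ""),
                         f"voorrips_{part}", errors)
        if v is not None and v < 0:
            errors.append(f"voorrips_{part} negative")
            v = None
        voorrips[part] = v

    schooling = row.get("schooling_level", "").strip().lower()
    if schooling not in _SCHOOLING:
        errors.append(f"schooling_level not in {_SCHOOLING}: "
                      f"{row.get('schooling_level')!r}")
    ses = row.get("socioeconomic_level", "").strip().lower()
    if ses not in _SES:
        errors.append(f"socioeconomic_level not in {_SES}: "
                      f"{row.get('socioeconomic_level')!r}")

    distance = _parse_float(row.get("distance_m", ""), "distance_m", errors)
    if distance is not None and distance <= 0:
        errors.append("distance_m not positive")

    stops_val = _parse_float(row.get("stops", ""), "stops", errors)
    stops: Optional[int] = None
    if stops_val is not None:
        if stops_val < 0 or stops_val != int(stops_val):
            errors.append("stops not a nonnegative integer")
        else:
            stops = int(stops_val)

    vitals: dict[str, Optional[float]] = {}
    for name in ("hr_rest", "hr_end"):
        v = _parse_float(row.get(name, ""), name, errors)
        if v is not None and v <= 0:
            errors.append(f"{name} not positive")
            v = None
        vitals[name] = v
    for name in ("spo2_rest", "spo2_end"):
        vitals[name] = _check_range(
            _parse_float(row.get(name, ""), name, errors),
            name, *SPO2_RANGE, errors)
    for name in ("sbp_rest", "sbp_end", "dbp_rest", "dbp_end"):
        vitals[name] = _parse_float(row.get(name, ""), name, errors)
    for name in ("dyspnea_rest", "dyspnea_end"):
        vitals[name] = _check_range(
            _parse_float(row.get(name, ""), name, errors),
            name, *DYSPNEA_RANGE, errors)

    if errors:
        raise ValueError("; ".join(errors))

    walk = WalkTestMeasurements(
        distance_m=distance, stops=stops,
        hr_rest=vitals["hr_rest"], hr_end=vitals["hr_end"],
        spo2_rest=vitals["spo2_rest"], spo2_end=vitals["spo2_end"],
        sbp_rest=vitals["sbp_rest"], sbp_end=vitals["sbp_end"],
        dbp_rest=vitals["dbp_rest"], dbp_end=vitals["dbp_end"],
        dyspnea_rest=vitals["dyspnea_rest"], dyspnea_end=vitals["dyspnea_end"],
    )
    return ParticipantRecord(
        id=rid, group=group, sex=sex, age=age, height=height, weight=weight,
        bmi=bmi, parity=parity, pack_years=pack_years,
        voorrips_daily=voorrips["daily"], voorrips_sport=voorrips["sport"],
        voorrips_leisure=voorrips["leisure"],
        schooling_level=schooling, socioeconomic_level=ses, walk=walk,
    )


# ---------------------------------------------------------------------------
# CSV I/O

def read_cohort(path, schema_version: str = "1",
                allow_extra_columns: bool = False) -> Cohort:
    """Read and validate a cohort CSV.

    Every input row ends up either in ``records`` or in ``exclusion_log``
    (with a reason naming the offending field); row order is preserved.

    Parameters
    ----------
    path:
        CSV file with the documented header.
    schema_version:
        Schema identifier; only ``"1"`` is defined.
    allow_extra_columns:
        If false (default), a column outside the schema raises
        :class:`SchemaError`. If true, extra columns (e.g. optional
        biochemical variables) are ignored by validation.
    """
    if schema_version != "1":
        raise SchemaError(f"unknown schema version {schema_version!r}")

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        if not allow_extra_columns:
            extra = [c for c in header if c not in COHORT_COLUMNS]
            if extra:
                raise SchemaError(f"unknown column(s): {', '.join(extra)}")

        cohort = Cohort(provenance=str(path))
        seen_ids: set[str] = set()
        for i, row in enumerate(reader, start=2):
            rid = (row.get("id") or "").strip() or f"<row {i}>"
            try:
                record = _validate_row(row)
            except ValueError as exc:
                cohort.exclusion_log.append((rid, str(exc)))
                continue
            if record.id in seen_ids:
                cohort.exclusion_log.append((rid, "duplicate id"))
                continue
            seen_ids.add(record.id)
            cohort.records.append(record)
    return cohort


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, int):
        return str(value)
    return repr(float(value))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV such that ``read_cohort`` reproduces it.

    Floats are written with full precision (``repr``); absent parity is an
    empty cell, never 0; sex is written as 0/1.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in cohort.records:
            w = r.walk
            writer.writerow([
                r.id, r.group, r.sex, _fmt(r.age), _fmt(r.height),
                _fmt(r.weight), _fmt(r.bmi), _fmt(r.parity),
                _fmt(r.pack_years), _fmt(r.voorrips_daily),
                _fmt(r.voorrips_sport), _fmt(r.voorrips_leisure),
                r.schooling_level, r.socioeconomic_level,
                _fmt(w.distance_m), w.stops, _fmt(w.hr_rest), _fmt(w.hr_end),
                _fmt(w.spo2_rest), _fmt(w.spo2_end), _fmt(w.sbp_rest),
                _fmt(w.sbp_end), _fmt(w.dbp_rest), _fmt(w.dbp_end),
                _fmt(w.dyspnea_rest), _fmt(w.dyspnea_end),
            ])
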