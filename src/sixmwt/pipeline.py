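"""End-to-end analysis: read → standardize → derive → classify → compare.

Produces the per-participant metrics table, four group-comparison report
tables (demographics/aging, walk distance & work, heart rate, blood
pressure/SpO2/dyspnea + intolerance signs), odds ratios for abnormal walk
distance and chronotropic insufficiency, Hedges' g for the primary
outcome, and within-group Wilcoxon comparisons of chronological versus
fitness age — as CSV, markdown and a deterministic JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .classify import categorical_statuses, sign_profile
from .cohort import Cohort, read_cohort
from .metrics import compute_metrics
from .reference import get_coefficients
from .stats import (ComparisonResult, compare_counts, compare_numeric,
                    hedges_g, odds_ratio, wilcoxon_paired)
from .synthetic import CohortSpec, generate_cohort

__all__ = ["AnalysisConfig", "AnalysisError", "run_analysis"]

log = logging.getLogger("sixmwt")


class AnalysisError(RuntimeError):
    """A pipeline stage could not run; the message names the stage."""


@dataclass
class AnalysisConfig:
    """Options for one analysis run; defaults reproduce the study's
    reporting conventions (integer % mean changes, 1-dp odds ratios,
    3-dp effect sizes, 2-dp participant percentages)."""

    input_csv: Optional[str] = None
    generator_spec: Optional[CohortSpec] = None
    coefficient_set: str = "north_african"
    chi2_continuity_correction: bool = False
    zero_cell_policy: str = "haldane"
    round_cells: bool = True
    output_dir: str = "sixmwt_report"
    seed: int = 0
    include_pci: bool = True


def _round(value, digits: int, enabled: bool):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return round(value, digits) if enabled else value


def _int_round(value, enabled: bool):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(round(value)) if enabled else value


def _comparison_row(res: ComparisonResult, rounding: bool) -> dict:
    cs, gs = res.case_summary, res.control_summary
    row = {"variable": res.variable, "test": res.test}
    if cs is not None:
        row.update({
            "case_n": cs.n, "case_mean": cs.mean, "case_sd": cs.sd,
            "case_ci95_low": cs.ci95_low, "case_ci95_high": cs.ci95_high,
            "control_n": gs.n, "control_mean": gs.mean, "control_sd": gs.sd,
            "control_ci95_low": gs.ci95_low, "control_ci95_high": gs.ci95_high,
        })
    row["mean_change_pct"] = _int_round(res.mean_pct_change, rounding)
    row["statistic"] = res.statistic
    row["p_value"] = _round(res.p_value, 3, rounding)
    if res.effect_size_g is not None:
        row["hedges_g"] = _round(res.effect_size_g, 3, rounding)
        row["effect_label"] = res.effect_label
    return row


def _count_row(variable: str, table, res: ComparisonResult,
               rounding: bool) -> dict:
    n_case = table.a + table.b
    n_control = table.c + table.d
    return {
        "variable": variable, "test": res.test,
        "case_count": table.a,
        "case_pct": _round(100.0 * table.a / n_case, 2, rounding),
        "control_count": table.c,
        "control_pct": _round(100.0 * table.c / n_control, 2, rounding),
        "statistic": None if math.isnan(res.statistic) else res.statistic,
        "p_value": _round(res.p_value, 3, rounding),
    }


def _markdown_table(df: pd.DataFrame) -> str:
    df = df.fillna("")
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = []
        for v in row:
            if isinstance(v, float):
                cells.append(f"{v:.4g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def _load_cohort(config: AnalysisConfig) -> Cohort:
    if (config.input_csv is None) == (config.generator_spec is None):
        raise AnalysisError(
            "input: provide exactly one of input_csv or generator_spec")
    if config.input_csv is not None:
        return read_cohort(config.input_csv, allow_extra_columns=True)
    spec = dataclasses.replace(config.generator_spec, seed=config.seed)
    return generate_cohort(spec)


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns the JSON summary as a dict. Writes, under
    ``config.output_dir``: ``participant_metrics.csv``, four
    ``table*_ ... .csv`` report tables plus a combined ``report.md``,
    ``summary.json`` and ``run.log``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.perf_counter()
    try:
        log.info("config: %s", config)
        log.info("version: %s", __version__)

        cohort = _load_cohort(config)
        log.info("stage load: %d records, %d excluded (%.3fs)",
                 len(cohort), len(cohort.exclusion_log),
                 time.perf_counter() - t0)
        cases = cohort.group("case")
        controls = cohort.group("control")
        if len(cases) < 2 or len(controls) < 2:
            raise AnalysisError(
                "groups: need at least 2 participants per group "
                f"(got {len(cases)} cases, {len(controls)} controls)")

        coeffs = get_coefficients(config.coefficient_set)
        rounding = config.round_cells

        # --- per-participant metrics and flags ------------------------------
        t = time.perf_counter()
        metrics = {r.id: compute_metrics(r, coeffs, config.include_pci)
                   for r in cohort.records}
        signs = {r.id: sign_profile(r, metrics[r.id])
                 for r in cohort.records}
        cats = {r.id: categorical_statuses(r) for r in cohort.records}

        rows = []
        for r in cohort.records:
            row = {"id": r.id, "group": r.group, "sex": r.sex, "age": r.age}
            row.update({k: v for k, v in
                        dataclasses.asdict(metrics[r.id]).items()
                        if k != "id"})
            row.update({f"flag_{k}": v for k, v in
                        dataclasses.asdict(signs[r.id]).items() if k != "id"})
            row.update({k: v for k, v in
                        dataclasses.asdict(cats[r.id]).items() if k != "id"})
            rows.append(row)
        metrics_df = pd.DataFrame(rows)
        metrics_df.to_csv(out / "participant_metrics.csv", index=False)
        log.info("stage derive+classify: %d rows (%.3fs)",
                 len(metrics_df), time.perf_counter() - t)

        # --- group comparison tables ----------------------------------------
        t = time.perf_counter()

        def col(group, fn):
            return [fn(r, metrics[r.id]) for r in group]

        def numeric(name, fn, effect=False):
            return _comparison_row(
                compare_numeric(name, col(cases, fn), col(controls, fn),
                                with_effect_size=effect), rounding)

        def counts(name, fn):
            res, table = compare_counts(
                name, [fn(r, signs[r.id], cats[r.id]) for r in cases],
                [fn(r, signs[r.id], cats[r.id]) for r in controls],
                config.chi2_continuity_correction)
            return _count_row(name, table, res, rounding), table

        table1 = [
            numeric("chronological_age_years", lambda r, m: r.age),
            numeric("ecrmc_age_years", lambda r, m: m.ecrmc_age_years),
            numeric("delta_age_years", lambda r, m: m.delta_age_years),
            numeric("height_m", lambda r, m: r.height),
            numeric("weight_kg", lambda r, m: r.weight),
            numeric("bmi_kg_m2", lambda r, m: r.bmi),
            numeric("voorrips_total", lambda r, m: r.voorrips_total),
        ]
        t1_counts = [
            counts("woman", lambda r, s, c: r.sex == 1)[0],
            counts("smoker", lambda r, s, c: c.smoker)[0],
            counts("sedentary", lambda r, s, c: c.sedentary)[0],
            counts("low_schooling",
                   lambda r, s, c: r.schooling_level == "low")[0],
            counts("unfavorable_ses",
                   lambda r, s, c: r.socioeconomic_level == "unfavorable")[0],
            counts("high_parity",
                   lambda r, s, c: bool(c.high_parity))[0],
        ]
        for status in ("underweight", "normal", "overweight", "obese"):
            t1_counts.append(
                counts(f"corpulence_{status}",
                       lambda r, s, c, st=status: c.corpulence == st)[0])

        table2 = [
            numeric("6mwd_m", lambda r, m: r.walk.distance_m, effect=True),
            numeric("6mwd_pct_predicted",
                    lambda r, m: m.pct_predicted_6mwd, effect=True),
            numeric("6mww_m_kg", lambda r, m: m.walk_work_m_kg),
        ]

        table3 = [
            numeric("hr_rest_bpm", lambda r, m: r.walk.hr_rest),
            numeric("hr_rest_pct_mphr", lambda r, m: m.hr_rest_pct_mphr),
            numeric("hr_end_bpm", lambda r, m: r.walk.hr_end),
            numeric("hr_end_pct_mphr", lambda r, m: m.hr_end_pct_mphr),
            numeric("delta_hr_pct", lambda r, m: m.delta_hr_pct),
        ]
        chrono_row, chrono_table = counts(
            "chronotropic_insufficiency",
            lambda r, s, c: s.chronotropic_insufficiency)
        table3_counts = [chrono_row]

        table4 = [
            numeric("sbp_rest_mmhg", lambda r, m: r.walk.sbp_rest),
            numeric("sbp_end_mmhg", lambda r, m: r.walk.sbp_end),
            numeric("delta_sbp_pct", lambda r, m: m.delta_sbp_pct),
            numeric("dbp_rest_mmhg", lambda r, m: r.walk.dbp_rest),
            numeric("dbp_end_mmhg", lambda r, m: r.walk.dbp_end),
            numeric("delta_dbp_pct", lambda r, m: m.delta_dbp_pct),
            numeric("spo2_rest_pct", lambda r, m: r.walk.spo2_rest),
            numeric("spo2_end_pct", lambda r, m: r.walk.spo2_end),
            numeric("delta_spo2_pct", lambda r, m: m.delta_spo2_pct),
            numeric("dyspnea_end_vas", lambda r, m: r.walk.dyspnea_end),
            numeric("spo2_change_points",
                    lambda r, m: m.spo2_change_points),
        ]
        abn_row, abn_table = counts(
            "abnormal_6mwd", lambda r, s, c: s.abnormal_6mwd)
        table4_counts = [
            counts("desaturation", lambda r, s, c: s.desaturation)[0],
            counts("high_dyspnea_end", lambda r, s, c: s.high_dyspnea_end)[0],
            counts("stopped_during_walk",
                   lambda r, s, c: s.stopped_during_walk)[0],
            abn_row,
        ]
        if config.include_pci:
            table3.append(numeric("pci_beats_per_m",
                                  lambda r, m: m.pci_beats_per_m))

        # Odds ratios for the two headline risk outcomes.
        def _or_entry(table):
            try:
                res = odds_ratio(table, config.zero_cell_policy)
            except ValueError as exc:
                return {"error": str(exc)}
            return {
                "odds_ratio": _round(res.odds_ratio, 1, rounding),
                "ci95_low": _round(res.ci95_low, 2, rounding),
                "ci95_high": _round(res.ci95_high, 2, rounding),
                "haldane_applied": res.haldane_applied,
            }

        odds = {"abnormal_6mwd": _or_entry(abn_table),
                "chronotropic_insufficiency": _or_entry(chrono_table)}

        # Within-group aging comparison (chronological vs fitness age).
        aging = {}
        for gname, grp in (("case", cases), ("control", controls)):
            res = wilcoxon_paired([r.age for r in grp],
                                  [metrics[r.id].ecrmc_age_years for r in grp])
            aging[gname] = {
                "statistic": res.statistic,
                "p_value": _round(res.p_value, 3, rounding),
                "n_nonzero": res.n_nonzero,
                "degenerate": res.degenerate,
            }
        log.info("stage compare: 4 tables (%.3fs)", time.perf_counter() - t)

        # --- write report bundle --------------------------------------------
        t = time.perf_counter()
        tables = {
            "table1_characteristics": pd.DataFrame(table1 + t1_counts),
            "table2_walk_distance_work": pd.DataFrame(table2),
            "table3_heart_rate": pd.DataFrame(table3 + table3_counts),
            "table4_bp_spo2_dyspnea_signs": pd.DataFrame(table4
                                                         + table4_counts),
        }
        md_parts = [f"# Walk-test case-control report\n\n"
                    f"sixmwt {__version__}; seed {config.seed}; "
                    f"{len(cases)} cases / {len(controls)} controls\n"]
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
            md_parts.append(f"\n## {name}\n\n" + _markdown_table(df))
        (out / "report.md").write_text("".join(md_parts), encoding="utf-8")

        g_m = next(r for r in table2 if r["variable"] == "6mwd_m")
        summary = {
            "version": __version__,
            "seed": config.seed,
            "n_case": len(cases),
            "n_control": len(controls),
            "n_excluded": len(cohort.exclusion_log),
            "exclusions": [list(e) for e in cohort.exclusion_log],
            "odds_ratios": odds,
            "hedges_g_6mwd_m": g_m.get("hedges_g"),
            "effect_label_6mwd_m": g_m.get("effect_label"),
            "sign_prevalence_pct": {
                row["variable"]: {"case": row["case_pct"],
                                  "control": row["control_pct"]}
                for row in table3_counts + table4_counts
            },
            "aging_wilcoxon": aging,
            "tables": {name: [
                {k: (None if isinstance(v, float) and math.isnan(v) else v)
                 for k, v in row.items()}
                for row in df.to_dict(orient="records")]
                for name, df in tables.items()},
        }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True,
                      allow_nan=False, default=_json_default)
            fh.write("\n")
        log.info("stage report: written to %s (%.3fs)", out,
                 time.perf_counter() - t)
        log.info("done in %.3fs", time.perf_counter() - t0)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _json_default(value):
    if isinstance(value, float) and math.isnan(value):
        return None
    if hasattr(value, "item"):
        return value.item()
    raise TypeError(f"not JSON serializable: {value!r}")
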