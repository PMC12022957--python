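"""Synthetic cohort generator: determinism, moments, prevalences,
spec validation, effect-recovery harness."""

import dataclasses

import numpy as np
import pytest

from sixmwt import (calibration_preset, design_point_preset,
                    effect_recovery_experiment, generate_cohort,
                    null_preset, read_cohort, write_cohort)
from sixmwt.synthetic import GroupSpec, SpecError


def test_preset_matches_study_composition():
    preset = calibration_preset()
    assert preset.case.n == 26
    assert preset.control.n == 28
    assert preset.case.distance == (641.0, 57.0)
    assert preset.control.distance == (702.0, 60.0)
    preset.validate()   # the preset is itself a valid GroupSpec pair


def test_group_sizes_and_sex_split(calibration_cohort):
    cases = calibration_cohort.group("case")
    controls = calibration_cohort.group("control")
    assert (len(cases), len(controls)) == (26, 28)
    assert sum(r.sex for r in cases) == 11        # women among cases
    assert sum(r.sex for r in controls) == 13


def test_same_seed_identical_csv_bytes(tmp_path):
    spec = calibration_preset(seed=42)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(generate_cohort(spec), p1)
    write_cohort(generate_cohort(spec), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seeds_differ(tmp_path):
    a = generate_cohort(calibration_preset(seed=1))
    b = generate_cohort(calibration_preset(seed=2))
    assert [r.walk.distance_m for r in a.records] != \
        [r.walk.distance_m for r in b.records]


def test_moment_convergence_at_large_n():
    """Sample moments within 2 % of the spec for wide-bound variables."""
    preset = calibration_preset(seed=9)
    case = dataclasses.replace(preset.case, n=10_000)
    control = dataclasses.replace(preset.control, n=10_000)
    cohort = generate_cohort(dataclasses.replace(preset, case=case,
                                                 control=control))
    for group, spec in (("case", case), ("control", control)):
        records = cohort.group(group)
        for getter, (mean, sd) in (
                (lambda r: r.walk.distance_m, spec.distance),
                (lambda r: r.height, spec.height)):
            values = np.array([getter(r) for r in records])
            assert np.mean(values) == pytest.approx(mean, rel=0.02)
            assert np.std(values, ddof=1) == pytest.approx(sd, rel=0.02)


def test_prevalence_convergence_at_large_n():
    """Bernoulli traits land inside the binomial 99 % CI of their spec."""
    preset = calibration_preset(seed=4)
    case = dataclasses.replace(preset.case, n=10_000)
    cohort = generate_cohort(dataclasses.replace(preset, case=case,
                                                 control=preset.control))
    records = cohort.group("case")
    n = len(records)
    for value, prob in (
            (np.mean([r.pack_years >= 5 for r in records]),
             case.smoker_prob),
            (np.mean([r.schooling_level == "low" for r in records]),
             case.low_schooling_prob),
            (np.mean([r.socioeconomic_level == "unfavorable"
                      for r in records]), case.unfavorable_ses_prob)):
        half = 2.576 * np.sqrt(prob * (1 - prob) / n)
        assert abs(value - prob) <= half


def test_distance_hr_end_correlation():
    preset = calibration_preset(seed=6)
    case = dataclasses.replace(preset.case, n=10_000)
    cohort = generate_cohort(dataclasses.replace(preset, case=case,
                                                 control=preset.control))
    records = cohort.group("case")
    d = [r.walk.distance_m for r in records]
    h = [r.walk.hr_end for r in records]
    rho = np.corrcoef(d, h)[0, 1]
    assert rho == pytest.approx(0.4, abs=0.05)


def test_sd_zero_gives_constant_column():
    preset = calibration_preset(seed=2)
    case = dataclasses.replace(preset.case, hr_rest=(70.0, 0.0))
    cohort = generate_cohort(dataclasses.replace(preset, case=case))
    assert all(r.walk.hr_rest == 70.0 for r in cohort.group("case"))


def test_infeasible_truncation_is_spec_error():
    preset = calibration_preset()
    bad = dataclasses.replace(preset.case, age=(42.0, 6.0, 50.0, 60.0))
    with pytest.raises(SpecError):
        dataclasses.replace(preset, case=bad).validate()
    with pytest.raises(SpecError):
        dataclasses.replace(preset.case, smoker_prob=1.5).validate()


def test_generated_cohort_passes_validation_roundtrip(tmp_path,
                                                      calibration_cohort):
    """Pipeline smoke property: generated cohorts validate cleanly."""
    path = tmp_path / "c.csv"
    write_cohort(calibration_cohort, path)
    cohort = read_cohort(path)
    assert len(cohort) == 54
    assert cohort.exclusion_log == []


def test_effect_recovery_requires_replicates():
    with pytest.raises(ValueError):
        effect_recovery_experiment(null_preset(), replicates=10, seed=0)


def test_effect_recovery_tracks_closed_form_power():
    """Empirical Mann-Whitney power at the design point (391 vs 421 m,
    SD 50, 27 per group) sits within a few points of the closed-form
    noncentral-t power for that configuration, 0.609."""
    import scipy.stats as sps

    n, d, s = 27, 31.0, 50.0
    ncp = d / (s * np.sqrt(2 / n))
    tcrit = sps.t.ppf(0.975, 2 * n - 2)
    oracle = float(sps.nct.sf(tcrit, 2 * n - 2, ncp)
                   + sps.nct.cdf(-tcrit, 2 * n - 2, ncp))
    assert oracle == pytest.approx(0.609, abs=0.001)
    report = effect_recovery_experiment(design_point_preset(),
                                        replicates=600, seed=12)
    assert report.power == pytest.approx(oracle, abs=0.07)


def test_effect_recovery_separates_null_from_design_point():
    """Cheap direction check: rejection rate at the design point clearly
    exceeds the null rate (full calibration lives in the deeper suite)."""
    null = effect_recovery_experiment(null_preset(), replicates=150, seed=3)
    effect = effect_recovery_experiment(design_point_preset(),
                                        replicates=150, seed=3)
    assert 0.0 <= null.power <= 0.15
    assert effect.power > null.power + 0.2
    assert null.ci95_low <= null.power <= null.ci95_high
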