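# Methods

## Scope and data model

The package standardizes six-minute walk test (6MWT) measurements
against population reference equations, derives per-participant capacity
and aging metrics, classifies exercise-intolerance signs, and compares a
case group against controls with nonparametric statistics. The unit of
analysis is one participant: demographics (sex coded 0 = man / 1 =
woman, the convention the reference equations were published with), age,
height, weight, BMI, parity (women only), pack-years, the three Voorrips
physical-activity sub-scores, schooling and socioeconomic level, and
paired rest/end walk-test vitals (HR, SpO2, systolic/diastolic blood
pressure, 0–10 dyspnea VAS) plus the distance walked and stop count.

Validation is total: every CSV row ends either in the cohort or in an
exclusion log with a machine-readable reason naming the field (e.g.
`spo2_end out of [50,100]`); nothing is silently dropped and nothing is
imputed. This mirrors the listwise-exclusion handling of incomplete
files in the study the calibration preset emulates. Height is stored in
metres; the reader accepts centimetres (values > 3 are divided by 100)
because the 40-plus distance equation needs metres. A stated BMI must
agree with weight/height² within 0.5 kg/m², otherwise the row is
excluded rather than silently recomputed. The original study's Excel
deposit is not parsed; converting it to the documented CSV schema is a
one-off column-renaming exercise left to the user.

## Reference equations

Two age branches for predicted distance and fitness age, with the
40-year boundary assigned to the 40-plus branch for **both** equation
families. The two source formulations word the boundary differently
("older than 40" for distance, "aged 40 years and more" for fitness
age); using one convention keeps a participant's prediction and fitness
age on the same branch. Exact (not truncated) age is used at the
boundary. No continuity across the branch point is claimed — the source
equations genuinely disagree there (the two LLN offsets alone differ by
14.69 m).

Fitness ("ECRMC") age can leave the plausible human range for extreme
distances — the emulated study's control mean of 25 ± 28 years implies
negative individual values in the real data — so values outside
[0, 120] years are returned unchanged and flagged, never clipped.

Coefficients live in a named registry (`CoefficientSet`), serializable
to JSON, so equations for other populations can be added without code
changes; the defaults are the North African set.

## Derived metrics and classification

Sign conventions: the SpO2 *drop* is rest − end so that "drop > 5
points" reads as desaturation; the signed end − rest change is kept
alongside it because published tables often print that orientation. The
rest-to-end relative deltas are 100·(End − Rest)/Rest; no delta is
defined for dyspnea because the resting VAS is 0 (the absolute end value
is reported instead). The physiological cost index divides the HR rise
by walking speed in m/min, giving beats per metre, the unit of the cited
healthy band 0.23–0.42.

All sign thresholds are strict inequalities as defined (`<` LLN, `<` 60
%MPHR, `>` 5 points, `>` 5/10); boundary values therefore never flag,
which the tests pin down. The smoker threshold is the inclusive
≥ 5 pack-years. The published corpulence bins ("18.5–24.9", "25–29.9")
leave [24.9, 25) formally unassigned; the package uses half-open bins
[18.5, 25) and [25, 30) so the BMI axis is partitioned. High parity is
*more than two* children and is not-applicable (`None`) for men — never
silently `False`.

## Group statistics

- **Summaries**: mean, SD (n − 1), t-based 95 % CI, median and quartiles
  by linear interpolation (numpy's default; the original study's
  software convention for quartiles is unknown, so no identity with it
  is claimed). The Shapiro-Wilk test (SciPy's implementation) gates
  whether a variable is *presented* as mean ± SD or median (IQR); it
  does not change which test runs — between-group comparisons are always
  nonparametric. Constant samples skip the gate (W is undefined at zero
  variance) and degenerate to a point CI.
- **Mann-Whitney U**: midrank-based U oriented on the first sample.
  Exact two-sided p by enumerating the null distribution (classic
  count recurrence) when n₁·n₂ ≤ 400 with no ties; otherwise a normal
  approximation with tie-corrected variance and a 0.5 continuity
  correction. Exact and asymptotic p agree within 0.02 from about 8 per
  group (tested).
- **Wilcoxon matched pairs**: zero differences dropped, midranks on
  tied magnitudes, statistic min(W⁺, W⁻); exact enumeration of sign
  assignments when ≤ 25 tie-free pairs remain, else the tie-corrected
  normal approximation. All-tied input returns a flagged degenerate
  result (statistic 0, p = 1) rather than an error.
- **χ²**: Pearson without continuity correction by default — this
  reproduces the emulated study's p = 0.033 for its 6/26-vs-1/28 table —
  with Yates' correction as an option; a flag marks expected counts
  below 5. Degenerate sign tables (outcomes nobody has) are reported
  with p = 1 rather than erroring, so zero-prevalence report rows still
  print.
- **Mean percentage change** is 100·(case − control)/case — the *case*
  mean is the denominator, which is why a −11 vs +12 year delta-age pair
  yields +209 %.
- **Odds ratio**: (a·d)/(b·c) with a Woolf log-normal 95 % CI (an
  extension: the emulated study prints point estimates only). Zero
  cells either raise or receive the Haldane-Anscombe +0.5 to all cells,
  per policy; the pipeline default is Haldane so reports always carry a
  number plus an `haldane_applied` marker.
- **Hedges' g**: pooled-SD standardized difference shrunk by
  J = 1 − 3/(4(n₁+n₂) − 9). Magnitude labels anchor at small ≤ 0.2,
  medium ≈ 0.5, large ≈ 0.8, very large ≥ 1.30; the boundaries between
  anchors are set at 0.2 / 0.65 / 1.30. By this scale the calibration
  moments give g = −1.026, "large".
- **Sample size**: N = (r+1)(Z_{α/2}+Z_{1−β})² s² / (r d²), split r : 1
  with fractional group sizes floored (the only convention consistent
  with reading 54.62 → 27 + 27) and the attrition revision rounded up,
  n_revised = ⌈n_total/(1 − attrition)⌉.

### A note on the design's power

Read against the standard two-sample derivation, the N produced by the
formula above corresponds to the *per-group* size, not the total. The
design point d = 31 m, s = 50 m read as 27 *per group* therefore has a
true two-sided t-test power of ≈ 0.61 (noncentral-t closed form), not
the nominal 90 % — about 55 per group would be needed for 90 %. The
simulation harness measures exactly this: the empirical Mann-Whitney
rejection rate at the design point lands within a few points of the 0.61
closed form (slightly below, as expected from the test's asymptotic
efficiency under normal shifts), and the package reports it as measured.

## Synthetic cohort generator

The generator exists so the full pipeline is exercisable and testable
without patient data. Continuous variables are truncated normals at the
spec'd mean/SD inside fixed physiologic bounds (SpO2 ≤ 100, dyspnea in
[0, 10], distance ≥ 200 m, etc.); binary traits are Bernoulli; the
number of women per group is fixed at round(n·fraction) so the
calibration preset reproduces the study's 11/26 and 13/28 sex split
exactly. Walk distance and end-of-walk HR are drawn jointly through a
Gaussian copula with rank correlation 0.4 — a plausibility choice (the
true correlation is unpublished) expressing the chronotropic link.
Parity is a rounded truncated normal; pack-years are drawn conditional
on smoker status (≥ 5 for smokers, < 5 otherwise); the three Voorrips
sub-scores are a fixed 0.55/0.22/0.23 split of the drawn total (the
case group's component proportions), since only the total drives
classification.

Seeding: one master seed; each (group, variable) pair derives its own
`SeedSequence` substream, so a fixed spec + seed is bit-reproducible and
adding a new variable cannot perturb existing columns.

**What the preset matches and what it does not.** Group sizes, sex
split, and every published group mean/SD and trait prevalence are
matched marginally; chronotropic insufficiency, desaturation and high
dyspnea prevalences emerge at study-like rates because they are driven
directly by those marginals. Variables other than (distance, HR_End) are
independent *within* group — in particular distance is independent of
sex and anthropometrics. Real walk distances co-vary strongly with both,
so the abnormal-distance flag (which compares distance to a
sex/anthropometrics-dependent LLN) is over-produced relative to the
emulated study (roughly 2–5× the published 34.6 %/3.6 % prevalences,
varying by seed), and per-participant quantities that mix distance with
anthropometrics (percent-predicted, fitness age) have wider spreads than
published. Passing tests on this generator therefore demonstrate
correctness of the computational pipeline under known marginals, not
fidelity of joint clinical structure. BMI is computed from the drawn
height and weight, so its SD is not separately controlled.

## Problem sizes and runtime choices

Moment-convergence checks use 10,000 participants per group (sampling
error ≈ 1 % of an SD, comfortably inside the 2 % assertion). The type-I
calibration uses 2,000 null replicates of the 26/28 design
(binomial SE ≈ 0.5 points at the nominal 5 %); power at the design
point uses 1,000 replicates (SE ≈ 1.6 points). The acceptance script
runs the same sizes and completes in well under a minute on one CPU.

## Known limitations

- The reference equations are constants taken from their publication;
  no re-derivation from normative data is attempted, and their validity
  outside North African adults is not the package's claim.
- No multiplicity adjustment and no covariate adjustment are applied —
  matching the emulated analysis, which used univariate nonparametric
  tests throughout.
- Quartile/tie conventions of legacy statistics packages are not
  replicated bit-for-bit; the package documents its own conventions.
- Two published mean-change cells (end HR in bpm, ΔSpO2) do not
  recompute from the rounded published group means; they are excluded
  from reproduction checks. Likewise the published effect size for
  percent-of-predicted distance (−0.980) is not recoverable from the
  printed moments (which give −0.779); only the metres value (−1.026)
  reproduces.
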