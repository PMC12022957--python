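# sixmwt

Standardization and case-control analysis of the six-minute walk test
(6MWT), the standard sub-maximal field test of aerobic capacity.

The package is aimed at clinical-physiology and epidemiology researchers
who collect 6MWT data in case-control designs (the built-in calibration
preset emulates a chronic-hepatitis-B vs healthy-control study, 26 vs 28
participants) and want a reproducible path from raw per-participant
measurements to publication-style comparison tables — without sharing
patient-level data, thanks to a seeded synthetic cohort generator.

## What it computes

**Reference standardization** (North African adult equations, sex coded
0 = man / 1 = woman, branched at age 40):

- predicted distance, under 40:
  `6MWD = 800.05 − 64.71·Sex − 10.23·BMI − 1.63·Age + 2.05·Weight`,
  and from 40 on:
  `6MWD = 720.50 − 160.27·Sex − 5.14·Age − 2.23·Weight + 271.98·Height(m)`;
- lower limit of normal (LLN): predicted − 74.31 m (< 40) or − 89 m (≥ 40);
- fitness ("ECRMC") age, under 40:
  `184.25 − 0.36·6MWD + 44.39·Height − 13.87·Sex`, from 40 on:
  `140.17 − 0.19·6MWD − 31.18·Sex − 0.43·Weight + 52.91·Height`;
- maximal predicted heart rate `MPHR = 208 − 0.7·Age`.

**Derived metrics**: % of predicted distance, walk work (6MWW = 6MWD ×
weight), rest-to-end deltas `Δ = 100·(End − Rest)/Rest` for HR, SpO2 and
blood pressure, SpO2 drop, HR as %MPHR, delta age (chronological −
fitness age), physiological cost index.

**Intolerance signs**: abnormal distance (6MWD < LLN), chronotropic
insufficiency (HR_End < 60 %MPHR), desaturation (SpO2 drop > 5 points),
high dyspnea (end VAS > 5/10), plus smoker / sedentary / corpulence /
parity categories.

**Group statistics**: Shapiro-Wilk gated summaries, Mann-Whitney U
(exact enumeration for small tie-free samples), 2-sided Pearson χ²,
Wilcoxon matched pairs, mean percentage change
`100·(case − control)/case`, odds ratios with Woolf intervals, Hedges'
bias-corrected g, and the two-sample design formula
`N = (r+1)(Z_{α/2}+Z_{1−β})² s² / (r d²)` with attrition revision.

## Worked example

Plan a 1:1 design to detect a 31 m distance difference (pooled SD 50 m)
at α = 0.05 and 90 % nominal power, with 10 % attrition:

```
$ sixmwt plan -s 50 -d 31 --attrition 0.10
raw N: 54.62
per group: 27 / 27
total: 54
revised for 10% attrition: 60
```

Generate a synthetic study-like cohort and analyze it:

```
$ sixmwt simulate --seed 1 --out cohort.csv
wrote 54 participants (26 cases, 28 controls) to cohort.csv
$ sixmwt analyze --input cohort.csv --out report --seed 1
report written to report (26 cases, 28 controls, 0 excluded)
```

`report/` now holds the per-participant metrics table, four
comparison tables (CSV + markdown), `summary.json` and a run log. For
this seed the walk-distance row of the distance/work table reads:

| variable | case mean±SD | control mean±SD | mean change | p | Hedges g |
|---|---|---|---|---|---|
| 6mwd_m | 668.0 ± 59.6 (n=26) | 686.1 ± 60.3 (n=28) | −3 % | 0.32 | −0.297 (medium) |

i.e. in this particular draw the simulated cases walked 18 m less than
controls — a medium, non-significant effect at n = 54 (single synthetic
cohorts scatter widely around the preset's 61 m gap; the published-moment
effect size `hedges_g(641, 57, 26, 702, 60, 28)` is −1.026, "large").
The same library calls are available in Python:

```python
from sixmwt import hedges_g, odds_ratio
from sixmwt.stats import ContingencyTable2x2

g, label = hedges_g(641, 57, 26, 702, 60, 28)   # (-1.026, "large")
res = odds_ratio(ContingencyTable2x2(9, 17, 1, 27))
res.odds_ratio                                   # 14.3
```

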