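"""Case-control statistical layer.

Group summaries with a Shapiro-Wilk normality gate, Mann-Whitney U
(exact enumeration for small tie-free samples, tie-corrected normal
approximation otherwise), Pearson chi-square on 2×2 tables, Wilcoxon
matched-pairs signed-rank, mean percentage change between group means,
odds ratios with Woolf confidence intervals, Hedges' bias-corrected
standardized mean difference g, and two-sample sample-size planning.

Mann-Whitney and Wilcoxon are implemented here because their contracts
(midranks, tie-corrected variance, exact enumeration cutoffs,
zero-difference handling) are part of this package's interface; SciPy
provides the underlying distributions (normal, t, chi-square) and the
Shapiro-Wilk procedure.

Conventions: U is reported for the first sample (x); the Wilcoxon
statistic is min(W+, W−); all p-values are two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ContingencyTable2x2",
    "ComparisonResult",
    "SampleSizePlan",
    "summarize",
    "mann_whitney_u",
    "chi2_test",
    "wilcoxon_paired",
    "mean_percentage_change",
    "odds_ratio",
    "hedges_g",
    "effect_label",
    "sample_size",
    "compare_numeric",
    "compare_counts",
]

# Exact-enumeration cutoffs (product of sample sizes for U; n of nonzero
# pairs for the signed-rank test). Beyond these, or with ties, the
# tie-corrected normal approximation with continuity correction is used.
MWU_EXACT_MAX_PRODUCT = 400
WILCOXON_EXACT_MAX_N = 25


# ---------------------------------------------------------------------------
# Summaries

@dataclass(frozen=True)
class GroupSummary:
    """Location/scale summary of one group's values for one variable."""

    n: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float
    median: float
    iqr_low: float
    iqr_high: float
    distribution_normal: bool
    shapiro_w: Optional[float] = None
    shapiro_p: Optional[float] = None


def summarize(sample: Iterable[float], alpha: float = 0.05) -> GroupSummary:
    """Mean ± SD with a t-based 95 % CI, median with quartiles, and a
    Shapiro-Wilk normality gate.

    SD uses the n−1 denominator; quartiles use the linear-interpolation
    convention (numpy default). A constant sample is treated as degenerate:
    the CI collapses to the mean and the normality gate passes trivially
    (the Shapiro-Wilk statistic is undefined at zero variance).
    """
    x = np.asarray(list(sample), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations to summarize")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return GroupSummary(n=n, mean=mean, sd=0.0, ci95_low=mean,
                            ci95_high=mean, median=mean, iqr_low=mean,
                            iqr_high=mean, distribution_normal=True)
    tcrit = float(sps.t.ppf(1 - alpha / 2, df=n - 1))
    half = tcrit * sd / math.sqrt(n)
    q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # small-n Shapiro p-value warnings
        w, p = sps.shapiro(x)
    return GroupSummary(n=n, mean=mean, sd=sd,
                        ci95_low=mean - half, ci95_high=mean + half,
                        median=med, iqr_low=q1, iqr_high=q3,
                        distribution_normal=bool(p > alpha),
                        shapiro_w=float(w), shapiro_p=float(p))


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _mwu_exact_sf_counts(m: int, n: int) -> np.ndarray:
    """Counts of arrangements giving each U value for samples of size m, n.

    Classic recurrence N(u; m, n) = N(u−n; m−1, n) + N(u; m, n−1): either
    the largest observation is from x (contributing n to U) or from y.
    """
    umax = m * n
    # table[i][j] = array of counts over u for sizes (i, j)
    prev = [np.array([1.0]) for _ in range(n + 1)]       # i = 0
    for i in range(1, m + 1):
        cur: list[np.ndarray] = [np.array([1.0])]        # j = 0 → U ≡ 0
        for j in range(1, n + 1):
            size = i * j + 1
            a = np.zeros(size)
            # largest rank in x: shift (i-1, j) counts by j
            sub = prev[j]
            a[j:j + sub.size] += sub
            # largest rank in y: (i, j-1) counts unshifted
            sub2 = cur[j - 1]
            a[:sub2.size] += sub2
            cur.append(a)
        prev = cur
    return prev[n]


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    U counts pairs (x_i, y_j) with x_i > y_j plus half the ties (midrank
    construction). The exact null distribution is enumerated when
    ``len(x)·len(y) ≤ 400`` and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction
    is used. ``method`` forces ``"exact"`` or ``"asymptotic"``.

    Returns ``(U, p)`` with U oriented on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be nonempty")

    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    rx = float(np.sum(ranks[:nx]))
    u = rx - nx * (nx + 1) / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if method == "auto":
        method = ("exact" if nx * ny <= MWU_EXACT_MAX_PRODUCT and not has_ties
                  else "asymptotic")
    if method == "exact":
        if has_ties:
            raise ValueError("exact enumeration requires tie-free samples")
        counts = _mwu_exact_sf_counts(nx, ny)
        total = counts.sum()
        ui = int(round(u))
        # two-sided: double the smaller tail (distribution is symmetric)
        lower = counts[: ui + 1].sum() / total
        upper = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return u, float(p)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    n = nx + ny
    mu = nx * ny / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u, 1.0
    z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(var) if u != mu else 0.0
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return u, min(1.0, p)


# ---------------------------------------------------------------------------
# Chi-square on a 2x2 table

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = group (case, control), columns = outcome (yes, no)."""

    a: int   # case, outcome present
    b: int   # case, outcome absent
    c: int   # control, outcome present
    d: int   # control, outcome absent

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("cell counts must be nonnegative integers")

    @classmethod
    def from_flags(cls, case_flags: Iterable[bool],
                   control_flags: Iterable[bool]) -> "ContingencyTable2x2":
        cf = [bool(v) for v in case_flags]
        gf = [bool(v) for v in control_flags]
        return cls(a=sum(cf), b=len(cf) - sum(cf),
                   c=sum(gf), d=len(gf) - sum(gf))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    low_expected_warning: bool


def chi2_test(table: ContingencyTable2x2,
              continuity_correction: bool = False) -> Chi2Result:
    """Two-sided Pearson chi-square (df = 1) on a 2×2 table.

    No continuity correction by default; Yates' correction is available.
    A warning flag is attached when any expected count is below 5.
    """
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    return Chi2Result(statistic=stat, p_value=p,
                      low_expected_warning=bool(np.any(expected < 5)))


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank

def _signed_rank_counts(ranks: Sequence[int]) -> np.ndarray:
    """Distribution of W+ over all 2^n sign assignments (integer ranks)."""
    total = int(sum(ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float   # min(W+, W−)
    p_value: float
    n_nonzero: int
    degenerate: bool   # every pair tied → no evidence either way


def wilcoxon_paired(before: Sequence[float], after: Sequence[float],
                    method: str = "auto") -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Zero differences are dropped; tied absolute differences get midranks.
    Exact enumeration of the 2^n sign assignments when the number of
    nonzero pairs is ≤ 25 and the midranks are tie-free; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValueError("paired samples must have equal length")
    if b.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_nonzero=0,
                              degenerate=True)

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    w_minus = float(np.sum(ranks[d < 0]))
    stat = min(w_plus, w_minus)

    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if method == "auto":
        method = ("exact" if n <= WILCOXON_EXACT_MAX_N and not has_ties
                  else "asymptotic")
    if method == "exact":
        if has_ties:
            raise ValueError("exact enumeration requires tie-free ranks")
        counts = _signed_rank_counts([int(r) for r in ranks])
        total = counts.sum()
        # two-sided: P(W+ ≤ min) + P(W+ ≥ max) over the symmetric null
        lo = int(round(stat))
        hi = int(round(max(w_plus, w_minus)))
        p = (counts[: lo + 1].sum() + counts[hi:].sum()) / total
        return WilcoxonResult(statistic=stat, p_value=min(1.0, float(p)),
                              n_nonzero=n, degenerate=False)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    mu = n * (n + 1) / 4.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var == 0:
        return WilcoxonResult(statistic=stat, p_value=1.0, n_nonzero=n,
                              degenerate=True)
    z = (w_plus - mu - math.copysign(0.5, w_plus - mu)) / math.sqrt(var) \
        if w_plus != mu else 0.0
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return WilcoxonResult(statistic=stat, p_value=p, n_nonzero=n,
                          degenerate=False)


# ---------------------------------------------------------------------------
# Effect measures

def mean_percentage_change(case_mean: float, control_mean: float) -> float:
    """Between-group mean change, 100·(case − control)/case.

    Note the case-group mean is the denominator.
    """
    if case_mean == 0:
        raise ZeroDivisionError("mean percentage change undefined for a "
                                "zero case-group mean")
    return 100.0 * (case_mean - control_mean) / case_mean


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    haldane_applied: bool


def odds_ratio(table: ContingencyTable2x2,
               zero_cell_policy: str = "error") -> OddsRatioResult:
    """Odds ratio (a·d)/(b·c) with a Woolf (log-normal) 95 % CI.

    ``zero_cell_policy``: ``"error"`` raises on any empty cell;
    ``"haldane"`` adds 0.5 to every cell when any is zero.
    """
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    haldane = False
    if min(a, b, c, d) == 0:
        if zero_cell_policy == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            haldane = True
        elif zero_cell_policy == "error":
            raise ValueError("odds ratio undefined with a zero cell "
                             "(use zero_cell_policy='haldane')")
        else:
            raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(sps.norm.ppf(0.975))
    return OddsRatioResult(
        odds_ratio=or_,
        ci95_low=math.exp(math.log(or_) - z * se),
        ci95_high=math.exp(math.log(or_) + z * se),
        haldane_applied=haldane,
    )


def effect_label(g: float) -> str:
    """Magnitude label for a standardized mean difference.

    Anchors: small ≤ 0.2, medium around 0.5, large around 0.8, very large
    ≥ 1.30; boundaries between the anchors are set at 0.2 / 0.65 / 1.30.
    """
    a = abs(g)
    if a <= 0.2:
        return "small"
    if a <= 0.65:
        return "medium"
    if a < 1.30:
        return "large"
    return "very_large"


def hedges_g(mean1: float, sd1: float, n1: int,
             mean2: float, sd2: float, n2: int) -> tuple[float, str]:
    """Hedges' bias-corrected standardized mean difference.

    g = J·(mean1 − mean2)/s_pooled with J = 1 − 3/(4(n1+n2) − 9) and
    s_pooled the n−1-weighted pooled SD. Returns (g, magnitude label).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("effect size undefined with zero pooled SD")
    d = (mean1 - mean2) / math.sqrt(pooled_var)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = d * j
    return g, effect_label(g)


# ---------------------------------------------------------------------------
# Sample-size planning

@dataclass(frozen=True)
class SampleSizePlan:
    """Two-sample mean-difference design resolved to whole participants."""

    z_alpha_half: float
    z_one_minus_beta: float
    r: float
    s: float
    d: float
    raw_n: float
    n_case: int
    n_control: int
    n_per_group: int
    n_total: int
    attrition: float
    n_revised: int


def sample_size(z_alpha_half: float, z_power: float, r: float,
                s: float, d: float, attrition: float = 0.0) -> SampleSizePlan:
    """Plan a two-group comparison of means.

    N = ((r+1)(Zα/2 + Z1−β)² s²) / (r d²) participants in total, split
    r : 1 between case and control; fractional group sizes are floored,
    and the attrition-revised total is rounded up:
    n_revised = ⌈n_total / (1 − attrition)⌉.
    """
    if d == 0:
        raise ValueError("required N is infinite for a zero mean difference")
    if s <= 0:
        raise ValueError("pooled SD must be positive")
    if not (0 <= attrition < 1):
        raise ValueError("attrition must be in [0, 1)")
    if r <= 0:
        raise ValueError("allocation ratio must be positive")
    raw_n = ((r + 1) * (z_alpha_half + z_power)**2 * s**2) / (r * d**2)
    n_control = math.floor(raw_n / (r + 1))
    n_case = math.floor(raw_n * r / (r + 1))
    n_total = n_case + n_control
    n_revised = math.ceil(n_total / (1.0 - attrition))
    return SampleSizePlan(
        z_alpha_half=z_alpha_half, z_one_minus_beta=z_power, r=r, s=s, d=d,
        raw_n=raw_n, n_case=n_case, n_control=n_control,
        n_per_group=n_control if n_case == n_control else min(n_case, n_control),
        n_total=n_total, attrition=attrition, n_revised=n_revised,
    )


# ---------------------------------------------------------------------------
# Per-variable comparison wrappers used by the pipeline

@dataclass(frozen=True)
class ComparisonResult:
    """Everything the report prints for one variable."""

    variable: str
    test: str                      # mann_whitney | chi2 | wilcoxon_paired
    case_summary: Optional[GroupSummary]
    control_summary: Optional[GroupSummary]
    statistic: float
    p_value: float
    mean_pct_change: Optional[float]
    effect_size_g: Optional[float] = None
    effect_label: Optional[str] = None


def compare_numeric(variable: str, case: Sequence[float],
                    control: Sequence[float],
                    with_effect_size: bool = False) -> ComparisonResult:
    """Mann-Whitney comparison of a numeric variable between groups."""
    cs = summarize(case)
    gs = summarize(control)
    u, p = mann_whitney_u(case, control)
    g = lab = None
    if with_effect_size:
        g, lab = hedges_g(cs.mean, cs.sd, cs.n, gs.mean, gs.sd, gs.n)
    change = (mean_percentage_change(cs.mean, gs.mean)
              if cs.mean != 0 else None)
    return ComparisonResult(variable=variable, test="mann_whitney",
                            case_summary=cs, control_summary=gs,
                            statistic=u, p_value=p, mean_pct_change=change,
                            effect_size_g=g, effect_label=lab)


def compare_counts(variable: str, case_flags: Sequence[bool],
                   control_flags: Sequence[bool],
                   continuity_correction: bool = False,
                   ) -> tuple[ComparisonResult, ContingencyTable2x2]:
    """Chi-square comparison of a binary trait between groups.

    Returns the comparison and the underlying 2×2 table (for odds ratios).
    Degenerate tables (an outcome nobody or everybody has) yield a
    NaN statistic and p = 1 rather than an error, so reports can still
    print the zero-prevalence rows.
    """
    table = ContingencyTable2x2.from_flags(case_flags, control_flags)
    try:
        res = chi2_test(table, continuity_correction)
        stat, p = res.statistic, res.p_value
    except ValueError:
        stat, p = float("nan"), 1.0
    return (ComparisonResult(variable=variable, test="chi2",
                             case_summary=None, control_summary=None,
                             statistic=stat, p_value=p,
                             mean_pct_change=None),
            table)
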