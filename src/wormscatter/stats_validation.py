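"""Cohort statistics and the scattering-vs-staining validation analysis.

Covers the statistics used to validate scattering density as a fat proxy:
per-condition summaries (mean, SEM, 95% t-CI), one-way ANOVA with
Bonferroni-corrected pairwise comparisons against a wild-type reference,
an unweighted OLS fit of cohort-mean staining density on cohort-mean
scattering density (with r² and a slope-zero test), paired before/after
fasting changes, and the fat-loss vs activity correlation.

The validation fit is on cohort means, not individual worms: scattering
and staining are measured on disjoint sets of worms from each cohort, so
no per-worm pairing exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CohortSummary:
    condition: str
    n: int
    mean: float
    sem: float
    ci95: tuple[float, float]


@dataclass
class AnovaResult:
    """One-way ANOVA F-test plus Bonferroni-adjusted pairwise comparisons."""

    f_stat: float
    p_value: float
    table: pd.DataFrame  # condition, p_raw, p_adjusted, significant
    reference: str
    n_comparisons: int


@dataclass
class ValidationFit:
    """OLS of mean staining density on mean scattering density across cohorts."""

    slope: float
    intercept: float
    r2: float
    p_slope: float
    points: list[tuple[float, float, float, float, str]] = field(default_factory=list)
    # (x_mean, x_sem, y_mean, y_sem, condition)


@dataclass
class PairedChangeResult:
    table: pd.DataFrame  # worm_id, before, after, delta, decreased
    n: int
    n_decreased: int
    fraction_decreased: float
    unmatched: list[str] = field(default_factory=list)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    degenerate: bool = False  # zero variance in one variable


def cohort_summary(values, condition: str) -> CohortSummary:
    """Mean, SEM (sample SD / sqrt(n)) and symmetric 95% t-CI of one cohort."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("cohort summary needs n >= 2 (SEM undefined otherwise)")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(n))
    half = float(sps.t.ppf(0.975, n - 1)) * sem
    return CohortSummary(condition=condition, n=n, mean=mean, sem=sem,
                         ci95=(mean - half, mean + half))


def anova_bonferroni(groups: dict[str, np.ndarray], reference: str,
                     all_pairs: bool = False, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA plus Bonferroni-corrected pairwise Welch t-tests.

    By default each non-reference condition is compared to the reference
    only, and the Bonferroni multiplier equals the number of those
    comparisons; ``all_pairs=True`` instead tests every pair.  Welch
    (unpooled-variance) t-tests are used because strain variances differ.
    """
    if reference not in groups:
        raise ValueError(f"reference condition {reference!r} not among groups")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        f_stat, p_value = 0.0, 1.0
        degenerate = True
    else:
        f_stat, p_value = sps.f_oneway(*arrays.values())
        degenerate = False
    if all_pairs:
        names = sorted(arrays)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    else:
        pairs = [(reference, c) for c in sorted(arrays) if c != reference]
    m = len(pairs)
    records = []
    for a, b in pairs:
        if degenerate or (np.all(arrays[a] == arrays[a][0]) and
                          np.all(arrays[b] == arrays[b][0]) and
                          arrays[a][0] == arrays[b][0]):
            p_raw = 1.0
        else:
            _, p_raw = sps.ttest_ind(arrays[a], arrays[b], equal_var=False)
            p_raw = float(p_raw)
        p_adj = min(1.0, p_raw * m)
        records.append({"condition": b if a == reference else f"{a} vs {b}",
                        "p_raw": p_raw, "p_adjusted": p_adj,
                        "significant": bool(p_adj < alpha)})
    return AnovaResult(f_stat=float(f_stat), p_value=float(p_value),
                       table=pd.DataFrame(records), reference=reference,
                       n_comparisons=m)


def validation_fit(cohorts: list[tuple[CohortSummary, CohortSummary]]) -> ValidationFit:
    """Fit mean staining density (y) on mean scattering density (x), one point per cohort.

    Ordinary least squares, unweighted (the per-cohort SEMs are reported
    alongside the points but do not weight the fit).  Returns r² (the
    squared Pearson correlation of the cohort means) and the two-sided p
    for the null hypothesis that the slope is zero.
    """
    if len(cohorts) < 3:
        raise ValueError("validation fit needs at least 3 cohorts")
    x = np.array([s.mean for s, _ in cohorts])
    y = np.array([o.mean for _, o in cohorts])
    if np.all(y == y[0]) or np.all(x == x[0]):
        # degenerate axis: flat fit, no explained variance
        slope, intercept = (0.0, float(y.mean())) if np.ptp(y) == 0 else (np.nan, np.nan)
        return ValidationFit(slope=slope, intercept=intercept, r2=0.0, p_slope=1.0,
                             points=[(s.mean, s.sem, o.mean, o.sem, s.condition)
                                     for s, o in cohorts])
    res = sps.linregress(x, y)
    return ValidationFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2, p_slope=float(res.pvalue),
        points=[(s.mean, s.sem, o.mean, o.sem, s.condition) for s, o in cohorts],
    )


def paired_change(before: list[tuple[str, float]],
                  after: list[tuple[str, float]]) -> PairedChangeResult:
    """Per-worm density change after an intervention (delta = after - before).

    A worm counts as "decreased" only for delta < 0 (no change is not a
    decrease).  Ids present on one side only are excluded from the summary
    and reported with a warning.
    """
    b = dict(before)
    a = dict(after)
    unmatched = sorted(set(b) ^ set(a))
    if unmatched:
        warnings.warn(f"{len(unmatched)} worm id(s) unmatched between before/after: "
                      f"{unmatched[:5]}{'...' if len(unmatched) > 5 else ''}")
    ids = sorted(set(b) & set(a))
    if not ids:
        raise ValueError("no matching worm ids between before and after")
    rows = [{"worm_id": w, "before": b[w], "after": a[w],
             "delta": a[w] - b[w], "decreased": a[w] - b[w] < 0} for w in ids]
    table = pd.DataFrame(rows)
    n_dec = int(table["decreased"].sum())
    return PairedChangeResult(table=table, n=len(ids), n_decreased=n_dec,
                              fraction_decreased=n_dec / len(ids),
                              unmatched=unmatched)


def activity_correlation(deltas: list[tuple[str, float]],
                         activity: list[tuple[str, float]]) -> CorrelationResult:
    """Pearson correlation between per-worm fat loss and locomotory activity."""
    d = dict(deltas)
    act = dict(activity)
    ids = sorted(set(d) & set(act))
    if len(ids) < 3:
        raise ValueError("need at least 3 matched worm pairs")
    x = np.array([d[w] for w in ids])
    y = np.array([act[w] for w in ids])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=len(ids),
                                 degenerate=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(ids))
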