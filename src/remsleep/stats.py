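"""Non-parametric cohort comparison workflow.

Sleep-metric distributions in clinical cohorts are typically non-normal
(a Shapiro-Wilk gate documents this per metric and group), so group
contrasts use two-tailed Mann-Whitney U tests, within-subject treatment
contrasts use Wilcoxon signed-rank tests, and each table's family of
p-values is corrected with the Bonferroni-Holm step-down procedure.
Summary tables report mean +/- SEM per cell, matching the convention of
clinical sleep papers.

Exact null distributions are used where sample size permits
(Mann-Whitney: both groups <= 20 and no ties; Wilcoxon: n <= 25 after
dropping zero differences), otherwise the normal approximation with
continuity and tie corrections.  Zero differences are dropped before
ranking (Wilcoxon's original treatment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSample

ALPHA_DEFAULT = 0.05

#: Metric families corrected together, mirroring the two results tables:
#: the baseline group-contrast family and the treatment-contrast family.
BASELINE_FAMILY = ("rl_minutes", "rd1", "total_night_rd")
TREATMENT_FAMILY = (
    "tst", "sws", "waso", "rem_time", "rem_percent", "rem_efficiency",
    "rl_minutes", "se",
)


@dataclass
class TestResult:
    metric: str
    test: str                      # "mann-whitney" or "wilcoxon"
    statistic: float
    z: Optional[float]
    p: float
    n: tuple                       # (n1, n2) or (n_pairs,)
    effect_direction: float        # sign: >0 means first group / baseline larger
    method: str = "asymptotic"     # "exact" or "asymptotic"
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None


@dataclass
class NormalityResult:
    metric: str
    group: str
    n: int
    W: float
    p: float


def normality_gate(values: Sequence[float], metric: str = "", group: str = "") -> NormalityResult:
    """Shapiro-Wilk normality check; advisory only — the pipeline always
    proceeds non-parametrically."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise DegenerateSample(f"need >= 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSample("constant sample: normality test undefined")
    W, p = _stats.shapiro(x)
    return NormalityResult(metric=metric, group=group, n=int(x.size), W=float(W), p=float(p))


def _mwu_z(x: np.ndarray, y: np.ndarray, U1: float) -> float:
    """Normal-approximation z for the Mann-Whitney U statistic with tie
    correction and continuity correction, signed so z > 0 when the first
    sample tends larger."""
    m, n = len(x), len(y)
    N = m + n
    pooled = np.concatenate([x, y])
    _, t = np.unique(pooled, return_counts=True)
    tie_term = ((t**3 - t).sum()) / (N * (N - 1)) if N > 1 else 0.0
    sigma2 = m * n / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return 0.0
    mu = m * n / 2.0
    diff = U1 - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    return float((diff - cc) / math.sqrt(sigma2))


def mann_whitney(x: Sequence[float], y: Sequence[float], metric: str = "") -> TestResult:
    """Two-tailed Mann-Whitney U test for independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise DegenerateSample("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and no_ties) else "asymptotic"
    res = _stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    U1 = float(res.statistic)
    z = _mwu_z(x, y, U1)
    # rank-biserial correlation sign gives the direction of the shift
    rb = 2.0 * U1 / (x.size * y.size) - 1.0
    return TestResult(
        metric=metric, test="mann-whitney", statistic=U1, z=z,
        p=float(res.pvalue), n=(int(x.size), int(y.size)),
        effect_direction=float(np.sign(rb)), method=method,
    )


def _wilcoxon_z(d: np.ndarray) -> float:
    """Signed-rank z with tie and continuity corrections (zeros already
    dropped); positive when differences tend positive."""
    n = d.size
    r = _stats.rankdata(np.abs(d))
    w_plus = r[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, t = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (t**3 - t).sum() / 48.0
    if sigma2 <= 0:
        return 0.0
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    return float((diff - cc) / math.sqrt(sigma2))


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], metric: str = ""
) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired samples ``a`` vs ``b``.

    ``effect_direction`` > 0 means ``a`` (e.g. baseline) tends larger than
    ``b``.  All-zero differences give the no-effect result p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise DegenerateSample("no complete pairs")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return TestResult(
            metric=metric, test="wilcoxon", statistic=0.0, z=0.0, p=1.0,
            n=(int(a.size),), effect_direction=0.0, method="exact",
        )
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) else "approx"
    res = _stats.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    z = _wilcoxon_z(d)
    return TestResult(
        metric=metric, test="wilcoxon", statistic=float(res.statistic), z=z,
        p=float(res.pvalue), n=(int(a.size),),
        effect_direction=float(np.sign(np.median(d)) or np.sign(z)),
        method="exact" if method == "exact" else "asymptotic",
    )


def compare_groups(
    cohort: pd.DataFrame,
    metric: str,
    night: str = "baseline",
    groups: tuple[str, str] = ("TRD", "HV"),
) -> TestResult:
    """Mann-Whitney contrast of ``metric`` between the two groups at one night."""
    sel = cohort[cohort["night"] == night]
    x = sel.loc[sel["group"] == groups[0], metric].to_numpy(dtype=float)
    y = sel.loc[sel["group"] == groups[1], metric].to_numpy(dtype=float)
    return mann_whitney(x, y, metric=metric)


def compare_paired(
    cohort: pd.DataFrame,
    metric: str,
    nights: tuple[str, str] = ("baseline", "post_treatment"),
    group: str = "TRD",
) -> TestResult:
    """Wilcoxon contrast of ``metric`` across nights within one group,
    matched by subject."""
    sel = cohort[cohort["group"] == group]
    wide = sel.pivot_table(index="subject_id", columns="night", values=metric,
                           aggfunc="first")
    if nights[0] not in wide.columns or nights[1] not in wide.columns:
        raise DegenerateSample(f"no paired {nights} data for group {group}")
    wide = wide.dropna(subset=list(nights))
    if wide.empty:
        raise DegenerateSample("no subject has both nights")
    return wilcoxon_signed_rank(
        wide[nights[0]].to_numpy(), wide[nights[1]].to_numpy(), metric=metric
    )


def holm_adjust(
    p_values: Sequence[float], alpha: float = ALPHA_DEFAULT
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-Holm step-down adjustment.

    Returns ``(p_adjusted, reject)``; adjusted p-values are monotone in the
    raw-p rank order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


def adjust_family(results: list[TestResult], alpha: float = ALPHA_DEFAULT) -> list[TestResult]:
    """Holm-adjust a family of test results in place and return it."""
    p_adj, reject = holm_adjust([r.p for r in results], alpha=alpha)
    for r, pa, rej in zip(results, p_adj, reject):
        r.p_adjusted = float(pa)
        r.significant = bool(rej)
    return results


def summary_table(
    cohort: pd.DataFrame,
    metrics: Sequence[str],
    grouping: Sequence[str] = ("group", "night"),
) -> pd.DataFrame:
    """Mean +/- SEM summary per metric and cell.

    Returns a long table with columns ``metric, <grouping...>, n, mean,
    sem, cell``; a single-observation cell carries ``sem = NaN`` and an
    empty cell is absent from the table.
    """
    rows = []
    for key, g in cohort.groupby(list(grouping), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        for m in metrics:
            vals = g[m].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else float("nan")
            cell = f"{mean:.2f} ± {sem:.2f}" if vals.size > 1 else f"{mean:.2f} ± NA"
            rows.append(
                dict(zip(grouping, key)) | {
                    "metric": m, "n": int(vals.size), "mean": mean,
                    "sem": sem, "cell": cell,
                }
            )
    return pd.DataFrame(rows, columns=[*grouping, "metric", "n", "mean", "sem", "cell"])
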