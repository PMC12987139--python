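"""Driver-level aggregation and the nonparametric group-comparison battery.

Analyses run at the driver level to avoid pseudoreplication: each driver's
repeated feature samples are collapsed to their median before any group
test.  The battery per feature is: descriptive statistics with t-based
confidence intervals, a normality screen (Kolmogorov-Smirnov with the
Lilliefors correction for estimated moments), a variance-homogeneity
screen (median-centred Levene, i.e. Brown-Forsythe), and — since the
physiological features fail those screens — the two-sided Mann-Whitney U
test as the primary group comparison, reported as median (P25, P75) plus
a signed Z and p.

Sign convention: Z > 0 when group D2 has the larger mean rank.  No
multiple-testing adjustment is applied across the nine features; each row
is reported at its nominal level (flagged in the report).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from omenscreen.cohort import CohortTable, DriverRecord, FEATURES

__all__ = [
    "DescriptiveRow",
    "GroupComparisonResult",
    "aggregate_driver_features",
    "compare_cohort",
    "comparison_frame",
    "descriptives",
    "descriptives_table",
    "ks_normality",
    "mann_whitney",
    "variance_homogeneity",
]

#: Total sample size at or below which the exact MWU null is enumerated.
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class DescriptiveRow:
    feature: str
    group: str
    n: int
    mean: float
    sd: float
    ci_lower: float | None
    ci_upper: float | None
    minimum: float
    maximum: float


@dataclass(frozen=True)
class GroupComparisonResult:
    feature: str
    median_a: float
    q25_a: float
    q75_a: float
    median_b: float
    q25_b: float
    q75_b: float
    z: float
    p: float
    n_a: int
    n_b: int
    test: str
    normality_p_a: float | None = None
    normality_p_b: float | None = None
    homogeneity_p: float | None = None


def aggregate_driver_features(samples, driver_id: str, label: str = "unknown") -> DriverRecord:
    """Collapse a driver's repeated samples to one median per feature.

    ``samples`` maps feature name to a sequence of values (or is a
    DataFrame with feature columns).  Features absent or empty are marked
    missing.
    """
    if isinstance(samples, pd.DataFrame):
        samples = {c: samples[c].dropna().to_numpy() for c in samples.columns}
    feats = {}
    any_values = False
    for name in FEATURES:
        vals = np.asarray(samples.get(name, []), dtype=float)
        if vals.size:
            feats[name] = float(np.median(vals))
            any_values = True
        else:
            feats[name] = None
    if not any_values:
        raise ValueError(f"driver {driver_id}: no feature samples to aggregate")
    return DriverRecord(driver_id=driver_id, label=label, features=feats)


def descriptives(values, feature: str = "", group: str = "") -> DescriptiveRow:
    """Mean, sample SD, t-based 95% CI of the mean, min and max."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("descriptives requires at least one value")
    mean = float(x.mean())
    if n >= 2:
        sd = float(x.std(ddof=1))
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        lo, hi = mean - half, mean + half
    else:
        sd, lo, hi = float("nan"), None, None
    return DescriptiveRow(
        feature=feature, group=group, n=n, mean=mean, sd=sd,
        ci_lower=lo, ci_upper=hi, minimum=float(x.min()), maximum=float(x.max()),
    )


def ks_normality(values, correction: str = "lilliefors"):
    """One-sample K-S normality test with moments estimated from the data.

    With ``correction="lilliefors"`` (default) the p-value comes from the
    Lilliefors null, which accounts for the estimated mean and SD; the
    plain K-S null (``correction="none"``) is anti-conservative in that
    setting and is kept only for comparison.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"normality test requires n >= 4, got {x.size}")
    if np.ptp(x) == 0.0:
        # Degenerate constant sample: maximal discrepancy, p below any floor.
        return 1.0, float(np.finfo(float).tiny)
    if correction == "lilliefors":
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    elif correction == "none":
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(stat), float(p)


def variance_homogeneity(group_a, group_b):
    """Brown-Forsythe test (median-centred Levene) for equal variances."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("variance homogeneity requires n >= 2 per group")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return 0.0, 1.0  # both degenerate: indistinguishable spreads
    stat, p = stats.levene(a, b, center="median")
    return float(stat), float(p)


def _tie_corrected_sd(pooled: np.ndarray, n_a: int, n_b: int) -> float:
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(max(var, 0.0))


def _u_statistic_b(pooled_ranks: np.ndarray, idx_b, n_b: int) -> float:
    return float(pooled_ranks[list(idx_b)].sum() - n_b * (n_b + 1) / 2.0)


def mann_whitney(group_a, group_b, feature: str = "") -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test of identical distributions.

    The U statistic counts pairs where a B value exceeds an A value (ties
    as half).  For total sample sizes up to
    :data:`EXACT_ENUMERATION_LIMIT` the two-sided p is obtained by exact
    enumeration of all group assignments of the pooled (mid-ranked)
    values, using the distance of U from its null mean as the ordering;
    larger samples use the normal approximation with tie and continuity
    corrections.  Z is reported from the normal approximation in both
    regimes, signed positive when group B has the larger mean rank.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_b = _u_statistic_b(ranks, range(n_a, n), n_b)
    mean_u = n_a * n_b / 2.0
    sd_u = _tie_corrected_sd(pooled, n_a, n_b)

    if sd_u == 0.0:
        z, p = 0.0, 1.0
        test = "mann-whitney (degenerate: all values tied)"
    else:
        dev = u_b - mean_u
        z = (dev - 0.5 * np.sign(dev)) / sd_u if dev != 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        test = "mann-whitney (normal approximation)"
        if n <= EXACT_ENUMERATION_LIMIT:
            obs = abs(dev)
            hits = total = 0
            for idx_b in itertools.combinations(range(n), n_b):
                u = _u_statistic_b(ranks, idx_b, n_b)
                total += 1
                if abs(u - mean_u) >= obs - 1e-12:
                    hits += 1
            p = min(hits / total, 1.0)
            test = "mann-whitney (exact enumeration)"
    p = min(p, 1.0)

    qa = np.percentile(a, [25, 50, 75])
    qb = np.percentile(b, [25, 50, 75])
    return GroupComparisonResult(
        feature=feature,
        median_a=float(qa[1]), q25_a=float(qa[0]), q75_a=float(qa[2]),
        median_b=float(qb[1]), q25_b=float(qb[0]), q75_b=float(qb[2]),
        z=float(z), p=float(p), n_a=n_a, n_b=n_b, test=test,
    )


def compare_cohort(cohort: CohortTable, features=FEATURES) -> list:
    """Per-feature screening battery over a labeled cohort.

    For each feature, runs the normality screen on both groups, the
    variance-homogeneity screen, and the Mann-Whitney comparison (group A
    = D1, group B = D2).  Raises if either group is absent.
    """
    frame = cohort.to_frame()
    d1 = frame[frame["group"] == "D1"]
    d2 = frame[frame["group"] == "D2"]
    if d1.empty or d2.empty:
        raise ValueError(
            f"cohort must contain both groups; got D1={len(d1)}, D2={len(d2)}"
        )
    results = []
    for feat in features:
        a = d1[feat].dropna().to_numpy()
        b = d2[feat].dropna().to_numpy()
        row = mann_whitney(a, b, feature=feat)
        norm_a = ks_normality(a)[1] if a.size >= 4 else None
        norm_b = ks_normality(b)[1] if b.size >= 4 else None
        hom = variance_homogeneity(a, b)[1] if min(a.size, b.size) >= 2 else None
        results.append(
            GroupComparisonResult(
                **{
                    **row.__dict__,
                    "normality_p_a": norm_a,
                    "normality_p_b": norm_b,
                    "homogeneity_p": hom,
                }
            )
        )
    return results


def comparison_frame(results) -> pd.DataFrame:
    """Long-format report: one row per feature x group, with shared Z and p.

    Note: p-values are per-feature at the nominal level; no adjustment for
    testing nine features is applied.
    """
    rows = []
    for r in results:
        for grp, med, q25, q75 in (
            ("D1", r.median_a, r.q25_a, r.q75_a),
            ("D2", r.median_b, r.q25_b, r.q75_b),
        ):
            rows.append(
                {
                    "feature": r.feature, "group": grp, "median": med,
                    "p25": q25, "p75": q75, "z": r.z, "p": r.p,
                }
            )
    return pd.DataFrame(rows)


def descriptives_table(cohort: CohortTable, features=FEATURES) -> pd.DataFrame:
    frame = cohort.to_frame()
    rows = []
    for feat in features:
        for grp in ("D1", "D2"):
            vals = frame.loc[frame["group"] == grp, feat].dropna().to_numpy()
            if vals.size == 0:
                continue
            d = descriptives(vals, feature=feat, group=grp)
            rows.append(d.__dict__)
    return pd.DataFrame(rows)
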