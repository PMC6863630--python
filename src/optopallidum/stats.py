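"""Population-level statistics for circuit-mapping cohorts.

Wraps the tests used to compare connection probabilities and response
amplitudes across cell classes: two-sided Fisher exact tests on 2x2
responder tables (with a Bonferroni family of four planned comparisons),
Wilcoxon rank-sum, Kruskal-Wallis with pairwise Tukey HSD, two-sample
Kolmogorov-Smirnov, and the one-sample signed-rank test against a reference
value (used for ratios expected to be 1).

Numerical engines come from scipy.stats; this module fixes the conventions
(sidedness, exact-vs-asymptotic switchover, tie handling, star annotation)
so every report in the package is produced the same way.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestReport",
    "fisher_exact_2x2",
    "bonferroni",
    "significance_stars",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "tukey_hsd",
    "ks_two_sample",
    "signed_rank_vs_value",
    "connection_table_analysis",
    "amplitude_comparison",
]

# Star levels follow the convention *, p<0.05; **, p<0.01; ***, p<0.001,
# divided by the size of the Bonferroni family when one applies.
BASE_STAR_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class ContingencyTable2x2:
    """Responder counts: rows are groups, columns responder/non-responder."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class TestReport:
    """Uniform record of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    n: tuple = ()
    adjusted_alpha: Optional[float] = None
    stars: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value out of range")


def significance_stars(p: float, m_comparisons: int = 1) -> str:
    """Star annotation at the conventional levels divided by the family size
    (e.g. family of 4: *, p<0.0125; **, p<0.0025; ***, p<0.00025)."""
    for stars, level in zip(("***", "**", "*"), sorted(BASE_STAR_LEVELS)):
        if p < level / m_comparisons:
            return stars
    return ""


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison alpha = alpha / m."""
    if not (0 < alpha <= 1) or m < 1:
        raise ValueError("need 0 < alpha <= 1 and m >= 1")
    return alpha / m


def fisher_exact_2x2(table: ContingencyTable2x2, sided: str = "two") -> TestReport:
    """Two-sided Fisher exact test by the point-probability rule (sum of
    hypergeometric probabilities of all tables with fixed margins whose point
    probability does not exceed the observed one)."""
    if sided != "two":
        raise ValueError("only the two-sided test is provided")
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        warnings.warn("empty margin: Fisher test degenerate, p = 1")
        return TestReport("fisher_exact", float("nan"), 1.0,
                          n=tuple(arr.sum(axis=1)))
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestReport("fisher_exact", float(odds), float(p), n=tuple(arr.sum(axis=1)))


def wilcoxon_rank_sum(x, y) -> TestReport:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestReport("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
                      n=(x.size, y.size), extras={"method": method})


def _kw_h(values: Sequence[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction (rank-based, all groups pooled)."""
    all_v = np.concatenate(values)
    ranks = sps.rankdata(all_v)
    n = all_v.size
    h = 0.0
    start = 0
    for v in values:
        r = ranks[start : start + v.size]
        h += r.sum() ** 2 / v.size
        start += v.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_v, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else float("nan")


def kruskal_wallis(groups: Sequence, labels: Optional[Sequence[str]] = None,
                   exact: bool = False) -> TestReport:
    """Kruskal-Wallis H test (tie-corrected) across two or more groups.

    The default reference distribution is chi-square with k-1 degrees of
    freedom; ``exact=True`` computes the permutation p-value by full
    enumeration of group assignments (small samples only, total n <= 10).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    h, p = sps.kruskal(*groups)
    if exact:
        n_total = sum(g.size for g in groups)
        if n_total > 10:
            raise ValueError("exact enumeration limited to total n <= 10")
        pooled = np.concatenate(groups)
        sizes = [g.size for g in groups]
        h_obs = _kw_h(groups)
        count = total = 0
        for perm in _group_assignments(n_total, sizes):
            parts = [pooled[list(ix)] for ix in perm]
            if _kw_h(parts) >= h_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    return TestReport("kruskal_wallis", float(h), float(p),
                      n=tuple(g.size for g in groups),
                      extras={"labels": list(labels) if labels else None,
                              "exact": exact})


def _group_assignments(n: int, sizes: Sequence[int]):
    """All ways to split indices 0..n-1 into ordered groups of given sizes."""
    idx = set(range(n))

    def rec(remaining, sizes_left):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for combo in itertools.combinations(sorted(remaining), k):
            for rest in rec(remaining - set(combo), sizes_left[1:]):
                yield (combo,) + rest

    yield from rec(idx, list(sizes))


def tukey_hsd(groups: Sequence, labels: Optional[Sequence[str]] = None) -> list:
    """All-pairs Tukey honestly-significant-difference comparisons
    (studentized-range reference on the group means)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = sps.tukey_hsd(*groups)
    labels = list(labels) if labels else [f"g{i}" for i in range(len(groups))]
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            out.append(TestReport(
                "tukey_hsd", float(res.statistic[i, j]), float(res.pvalue[i, j]),
                n=(groups[i].size, groups[j].size),
                extras={"pair": (labels[i], labels[j])}))
    return out


def ks_two_sample(x, y) -> TestReport:
    """Two-sample Kolmogorov-Smirnov test on cumulative distributions;
    exact for small samples, asymptotic otherwise (scipy's auto rule)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.ks_2samp(x, y, alternative="two-sided", method="auto")
    return TestReport("ks_two_sample", float(res.statistic), float(res.pvalue),
                      n=(x.size, y.size))


def signed_rank_vs_value(x, mu: float = 1.0) -> TestReport:
    """Two-sided Wilcoxon signed-rank test of a sample against a reference
    value (default 1, for normalized ratios). Zero differences are dropped
    with the sample size adjusted; exact null for n <= 20 without ties."""
    x = np.asarray(x, dtype=float)
    d = x - mu
    n_nonzero = int(np.sum(d != 0))
    if n_nonzero == 0:
        return TestReport("signed_rank", 0.0, 1.0, n=(0,),
                          extras={"dropped_zeros": int(x.size)})
    res = sps.wilcoxon(d[d != 0], alternative="two-sided",
                       zero_method="wilcox",
                       method="exact" if n_nonzero <= 20 else "approx")
    return TestReport("signed_rank", float(res.statistic), float(res.pvalue),
                      n=(n_nonzero,),
                      extras={"dropped_zeros": int(x.size - n_nonzero)})


# ---------------------------------------------------------------------------
# cohort-level reports

PLANNED_COMPARISONS = (
    # (fixed dimension, value, varying dimension, level_1, level_2)
    ("cortical_source", "M1", "projection_class", "GP_CPu", "GP_STN"),
    ("cortical_source", "M2", "projection_class", "GP_CPu", "GP_STN"),
    ("projection_class", "GP_STN", "cortical_source", "M1", "M2"),
    ("projection_class", "GP_CPu", "cortical_source", "M1", "M2"),
)


def _responder_counts(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-(cell, pulse) table to one row per cell with the
    connection call."""
    cols = ["cell_id", "projection_class", "cortical_source", "connected"]
    per_cell = measurements[cols].drop_duplicates("cell_id")
    return per_cell


def connection_table_analysis(measurements: pd.DataFrame,
                              alpha: float = 0.05) -> list:
    """Fisher exact tests on the four planned connection-probability
    comparisons (projection classes within each motor area, motor areas
    within each projection class), Bonferroni-corrected for the family of 4.

    ``measurements`` needs columns cell_id, projection_class,
    cortical_source, connected (the per-pulse table from the oEPSC pipeline
    works directly). Comparisons with an empty class are skipped with a
    warning.
    """
    per_cell = _responder_counts(measurements)
    m = len(PLANNED_COMPARISONS)
    adj = bonferroni(alpha, m)
    reports = []
    for fixed_dim, fixed_val, dim, v1, v2 in PLANNED_COMPARISONS:
        sub = per_cell[per_cell[fixed_dim] == fixed_val]
        g1 = sub[sub[dim] == v1]["connected"]
        g2 = sub[sub[dim] == v2]["connected"]
        if g1.empty or g2.empty:
            warnings.warn(f"skipping {fixed_val}: empty class {v1 if g1.empty else v2}")
            continue
        t = ContingencyTable2x2(int(g1.sum()), int((~g1).sum()),
                                int(g2.sum()), int((~g2).sum()))
        rep = fisher_exact_2x2(t)
        rep.adjusted_alpha = adj
        rep.stars = significance_stars(rep.p_value, m)
        rep.extras.update({"comparison": f"{fixed_val}: {v1} vs {v2}",
                           "counts": (t.a, t.b, t.c, t.d)})
        reports.append(rep)
    return reports


def amplitude_comparison(measurements: pd.DataFrame,
                         amplitude_col: str = "amplitude",
                         min_n: int = 2) -> dict:
    """Amplitude comparisons across cell classes.

    One-way ANOVA across {MSN, STN, GP_STN, GP_CPu} followed by all-pairs
    Tukey HSD, plus the rank-sum comparison of GP_CPu vs GP_STN and the
    Kolmogorov-Smirnov comparison of GP_Bi vs GP_CPu amplitude distributions
    when those classes are present. Uses the first-pulse amplitude of
    connected cells; classes with fewer than ``min_n`` cells are excluded
    with a warning.
    """
    first = measurements[(measurements.get("pulse", 0) == 0)
                         & measurements["connected"]]
    by_class = {}
    for cls, sub in first.groupby("projection_class"):
        vals = sub[amplitude_col].dropna().to_numpy()
        if vals.size < min_n:
            warnings.warn(f"excluding class {cls} with n={vals.size}")
            continue
        by_class[cls] = vals
    report: dict = {"group_n": {k: int(v.size) for k, v in by_class.items()}}
    anova_classes = [c for c in ("MSN", "STN", "GP_STN", "GP_CPu") if c in by_class]
    if len(anova_classes) >= 2:
        vals = [by_class[c] for c in anova_classes]
        f, p = sps.f_oneway(*vals)
        report["anova"] = TestReport("one_way_anova", float(f), float(p),
                                     n=tuple(v.size for v in vals),
                                     extras={"labels": anova_classes})
        report["tukey"] = tukey_hsd(vals, labels=anova_classes)
    if "GP_CPu" in by_class and "GP_STN" in by_class:
        report["gp_cpu_vs_gp_stn"] = wilcoxon_rank_sum(by_class["GP_CPu"],
                                                       by_class["GP_STN"])
    if "GP_Bi" in by_class and "GP_CPu" in by_class:
        report["gp_bi_vs_gp_cpu"] = ks_two_sample(by_class["GP_Bi"],
                                                  by_class["GP_CPu"])
    return report
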