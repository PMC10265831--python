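"""Group-comparison decision tree used throughout the analysis.

A parameter is gated for normality first: it counts as normally
distributed only if *no* group (across all conditions and regions
supplied) rejects at the chosen level.  The omnibus test is one-way ANOVA
on the normal branch and Kruskal-Wallis otherwise; post-hoc pairwise
comparisons use a two-tailed unpaired t-test or a Mann-Whitney U test on
the matching branch.  No multiple-testing correction is applied by default
(a flag exists).

The normality test is a Kolmogorov-Smirnov test against a normal with
estimated mean/SD using Lilliefors-corrected critical values — the plain
KS distribution would be anti-conservative when parameters are estimated
from the data.

Boxplot summaries report median, mean, 25th/75th percentiles (box) and
5th/95th percentiles (whiskers), with linear-interpolation quantiles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BoxplotSummary",
    "ComparisonResult",
    "GroupNormality",
    "NormalityVerdict",
    "OmnibusResult",
    "PairResult",
    "boxplot_summary",
    "compare_groups",
    "normality_gate",
    "omnibus",
    "posthoc_pairs",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Asterisk annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupNormality:
    group: str
    n: int
    statistic: float
    p_value: float
    included: bool
    degenerate: bool = False


@dataclass
class NormalityVerdict:
    normal: bool
    alpha: float
    per_group: list[GroupNormality] = field(default_factory=list)


@dataclass
class OmnibusResult:
    test: str
    statistic: float
    p_value: float


@dataclass
class PairResult:
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    stars: str = ""


@dataclass
class BoxplotSummary:
    median: float
    mean: float
    q25: float
    q75: float
    p5: float
    p95: float
    n: int


@dataclass
class ComparisonResult:
    verdict: NormalityVerdict
    omnibus: OmnibusResult
    pairwise: list[PairResult]
    summaries: dict[str, BoxplotSummary]


def _clean_groups(table: dict) -> dict[str, np.ndarray]:
    return {str(k): np.asarray(v, dtype=float) for k, v in table.items()}


def normality_gate(table: dict, alpha: float = 0.05) -> NormalityVerdict:
    """Lilliefors-corrected KS normality gate over all supplied groups.

    The parameter is "normal" only if every included group fails to reject
    at ``alpha``.  Groups with fewer than 3 values are excluded with a
    warning; constant (zero-variance) groups are degenerate and force a
    non-normal verdict.
    """
    groups = _clean_groups(table)
    per_group: list[GroupNormality] = []
    normal = True
    for name, values in groups.items():
        n = values.size
        if n < 4:  # the Lilliefors table starts at n = 4
            warnings.warn(
                f"group {name!r} has only {n} values and is excluded from "
                "the normality gate",
                stacklevel=2,
            )
            per_group.append(GroupNormality(name, n, np.nan, np.nan, included=False))
            continue
        if np.ptp(values) == 0:
            per_group.append(
                GroupNormality(name, n, np.nan, 0.0, included=True, degenerate=True)
            )
            normal = False
            continue
        stat, p = lilliefors(values, dist="norm", pvalmethod="table")
        per_group.append(GroupNormality(name, n, float(stat), float(p), included=True))
        if p < alpha:
            normal = False
    return NormalityVerdict(normal=normal, alpha=alpha, per_group=per_group)


def omnibus(table: dict, verdict: NormalityVerdict | bool) -> OmnibusResult:
    """One-way ANOVA on the normal branch, Kruskal-Wallis otherwise."""
    groups = _clean_groups(table)
    if len(groups) < 2:
        raise ValueError("omnibus testing needs at least 2 groups")
    normal = verdict.normal if isinstance(verdict, NormalityVerdict) else bool(verdict)
    samples = list(groups.values())
    if normal:
        stat, p = sps.f_oneway(*samples)
        return OmnibusResult("anova", float(stat), float(p))
    stat, p = sps.kruskal(*samples)
    return OmnibusResult("kruskal-wallis", float(stat), float(p))


def posthoc_pairs(
    table: dict,
    verdict: NormalityVerdict | bool,
    pairs=None,
    correction: str | None = None,
) -> list[PairResult]:
    """All unordered pairwise tests on the branch matching the verdict.

    Two-tailed unpaired t-test when normal, Mann-Whitney U otherwise.  No
    multiplicity correction by default; ``correction`` accepts any method
    name understood by statsmodels (e.g. ``"holm"``, ``"bonferroni"``).
    """
    groups = _clean_groups(table)
    normal = verdict.normal if isinstance(verdict, NormalityVerdict) else bool(verdict)
    if pairs is None:
        pairs = list(itertools.combinations(sorted(groups), 2))
    results = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"cannot compare group {a!r} with itself")
        if a not in groups or b not in groups:
            raise KeyError(f"unknown group in pair ({a!r}, {b!r})")
        if normal:
            stat, p = sps.ttest_ind(groups[a], groups[b], equal_var=True)
            test = "t-test"
        else:
            stat, p = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            test = "mann-whitney"
        results.append(PairResult(a, b, test, float(stat), float(p)))
    if correction is not None and results:
        adjusted = multipletests([r.p_value for r in results], method=correction)[1]
        for r, p_adj in zip(results, adjusted):
            r.p_value = float(p_adj)
    for r in results:
        r.stars = significance_stars(r.p_value)
    return results


def boxplot_summary(values) -> BoxplotSummary:
    """Median, mean, quartiles and 5th/95th percentiles of one group."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q = np.quantile(v, [0.05, 0.25, 0.5, 0.75, 0.95], method="linear")
    return BoxplotSummary(
        median=float(q[2]), mean=float(v.mean()),
        q25=float(q[1]), q75=float(q[3]),
        p5=float(q[0]), p95=float(q[4]), n=int(v.size),
    )


def compare_groups(
    table: dict,
    alpha: float = 0.05,
    run_posthoc: bool = True,
    gate_posthoc_on_omnibus: bool = False,
    correction: str | None = None,
) -> ComparisonResult:
    """Full decision tree: normality gate, omnibus, post-hocs, summaries.

    Post-hoc tests run regardless of omnibus significance by default
    (``gate_posthoc_on_omnibus`` makes them conditional).
    """
    verdict = normality_gate(table, alpha=alpha)
    result = omnibus(table, verdict)
    pairwise: list[PairResult] = []
    if run_posthoc and not (gate_posthoc_on_omnibus and result.p_value >= alpha):
        pairwise = posthoc_pairs(table, verdict, correction=correction)
    summaries = {str(k): boxplot_summary(v) for k, v in table.items()}
    return ComparisonResult(verdict, result, pairwise, summaries)
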