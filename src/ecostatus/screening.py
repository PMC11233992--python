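"""Sensitivity screening of indices between good and non-good references.

Each index is compared between the two labelled reference groups.  The
parametric route (Student's t-test) is taken only when both groups pass
Shapiro-Wilk normality and the pair passes Bartlett's homoscedasticity
test, all at alpha = 0.05; otherwise the two-sided Wilcoxon rank-sum
(Mann-Whitney) test is used — exact enumeration for small tie-free
groups, normal approximation with continuity correction otherwise.  No
multiple-testing correction is applied by default (a Holm flag exists).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GOOD, NON_GOOD
from .indices import IndexTable, UP_IN_GOOD, UP_IN_NON_GOOD, DIRECTION_UNKNOWN

logger = logging.getLogger("ecostatus")

T_TEST = "t_test"
WILCOXON = "wilcoxon"

#: Largest group size for which the rank-sum null is enumerated exactly.
EXACT_RANKSUM_MAX_N = 25


@dataclass
class AssumptionCheck:
    shapiro_p_good: float
    shapiro_p_non_good: float
    bartlett_p: float
    assumptions_met: bool


@dataclass
class ScreeningResult:
    """Outcome of one index's good vs non-good comparison."""

    index_name: str
    n_good: int
    n_non_good: int
    shapiro_p_good: float
    shapiro_p_non_good: float
    bartlett_p: float
    assumptions_met: bool
    test_used: str
    p_value: float
    significant: bool
    direction: str


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def check_assumptions(values_good, values_non_good, alpha: float = 0.05) -> AssumptionCheck:
    """Shapiro-Wilk per group and Bartlett across groups at level alpha.

    Assumptions are met only when all three p-values exceed alpha.
    Degenerate (constant) groups fail the check with NaN p-values.
    """
    g, n = _clean(values_good), _clean(values_non_good)
    if len(g) < 3 or len(n) < 3:
        raise ValueError("each group needs >= 3 finite values")
    if np.ptp(g) == 0 or np.ptp(n) == 0:
        return AssumptionCheck(math.nan, math.nan, math.nan, False)
    sp_g = float(stats.shapiro(g).pvalue)
    sp_n = float(stats.shapiro(n).pvalue)
    bp = float(stats.bartlett(g, n).pvalue)
    met = sp_g > alpha and sp_n > alpha and bp > alpha
    return AssumptionCheck(sp_g, sp_n, bp, met)


def _ranksum(g: np.ndarray, n: np.ndarray) -> float:
    has_ties = len(np.unique(np.concatenate([g, n]))) < len(g) + len(n)
    if max(len(g), len(n)) <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(g, n, alternative="two-sided", method=method).pvalue
    )


def compare_groups(
    values_good,
    values_non_good,
    index_name: str = "",
    alpha: float = 0.05,
    welch: bool = False,
) -> ScreeningResult:
    """Compare an index between the two reference groups.

    Student's (or, on request, Welch's) two-sided t-test when the
    normality and homoscedasticity gates pass, Wilcoxon rank-sum
    otherwise.  Direction is read from group means on the parametric
    route and group medians (ties broken by means) on the rank route.
    """
    g, n = _clean(values_good), _clean(values_non_good)
    chk = check_assumptions(g, n, alpha=alpha)
    if chk.assumptions_met:
        test_used = T_TEST
        p = float(stats.ttest_ind(g, n, equal_var=not welch).pvalue)
        loc_g, loc_n = float(np.mean(g)), float(np.mean(n))
    else:
        test_used = WILCOXON
        if np.array_equal(np.sort(g), np.sort(n)) or np.ptp(np.concatenate([g, n])) == 0:
            p = 1.0
        else:
            p = _ranksum(g, n)
        loc_g, loc_n = float(np.median(g)), float(np.median(n))
        if loc_g == loc_n:
            loc_g, loc_n = float(np.mean(g)), float(np.mean(n))
    if loc_g > loc_n:
        direction = UP_IN_GOOD
    elif loc_g < loc_n:
        direction = UP_IN_NON_GOOD
    else:
        direction = DIRECTION_UNKNOWN
    return ScreeningResult(
        index_name=index_name,
        n_good=len(g),
        n_non_good=len(n),
        shapiro_p_good=chk.shapiro_p_good,
        shapiro_p_non_good=chk.shapiro_p_non_good,
        bartlett_p=chk.bartlett_p,
        assumptions_met=chk.assumptions_met,
        test_used=test_used,
        p_value=p,
        significant=p < alpha,
        direction=direction,
    )


def screen(
    table: IndexTable,
    labels: dict[str, str],
    alpha: float = 0.05,
    correction: str = "none",
    welch: bool = False,
) -> tuple[list[ScreeningResult], list[str]]:
    """Screen every index of a table; return results and the sensitive set.

    ``labels`` maps sample_id to good/non_good; unlabeled samples are
    ignored.  Indices with fewer than 3 usable values in either group are
    skipped with a logged reason.  ``correction="holm"`` applies the Holm
    step-down adjustment before calling significance.
    """
    if correction not in ("none", "holm"):
        raise ValueError(f"unknown correction {correction!r}")
    good_ids = [s for s in table.sample_ids if labels.get(s) == GOOD]
    non_ids = [s for s in table.sample_ids if labels.get(s) == NON_GOOD]
    if not good_ids or not non_ids:
        raise ValueError("both reference labels (good, non_good) must be present")

    results: list[ScreeningResult] = []
    for name in table.index_names:
        col = table.frame[name]
        g = _clean(col.loc[good_ids])
        n = _clean(col.loc[non_ids])
        if len(g) < 3 or len(n) < 3:
            logger.info("index %s skipped: fewer than 3 usable values in a group", name)
            continue
        if np.ptp(g) == 0 and np.ptp(n) == 0 and g[0] == n[0]:
            logger.info("index %s skipped: constant across both groups", name)
            continue
        results.append(compare_groups(g, n, index_name=name, alpha=alpha, welch=welch))

    if correction == "holm":
        order = np.argsort([r.p_value for r in results])
        m = len(results)
        running_max = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * results[idx].p_value)
            running_max = max(running_max, adj)
            results[idx].p_value = running_max
            results[idx].significant = running_max < alpha

    sensitive = [r.index_name for r in results if r.significant]
    return results, sensitive


def results_frame(results: list[ScreeningResult]):
    import pandas as pd

    return pd.DataFrame([vars(r) for r in results])
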