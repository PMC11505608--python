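"""Group-comparison statistics for phenotype fractions and fluorescence.

Replicate-level summaries (e.g. percent of cells with an abnormal envelope)
are compared with t-tests: independent Student (equal-variance pooled) by
default, optionally Welch, or paired when the replicates are related (e.g.
intensities acquired with per-replicate exposure settings).  One-tailed
variants are used when the treatment is expected to act in a known direction.
Assumption checks (Shapiro-Wilk normality per group and a two-tailed
variance-ratio F test) are attached to every comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    group_names: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    ns: tuple[int, int]
    test: str  # "independent" | "welch" | "paired"
    direction: str  # "two-sided" | "greater" | "less"
    statistic: float
    p_value: float
    shapiro: tuple[tuple[float, float], tuple[float, float]]  # (W, p) per group
    f_statistic: float
    f_p_value: float


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def _variance_ratio_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed F test of equal variances, F = s_a² / s_b², df = (n−1, n−1)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if vb == 0 and va == 0:
        return float("nan"), float("nan")
    f = va / vb if vb > 0 else float("inf")
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(sps.f.sf(f, dfa, dfb), sps.f.cdf(f, dfa, dfb))
    return float(f), float(min(p, 1.0))


def compare_groups(
    a,
    b,
    test: str = "independent",
    direction: str = "two-sided",
    names: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Compare two numeric series with the chosen t-test variant.

    ``direction`` follows scipy: ``"greater"`` tests mean(a) > mean(b) (for a
    paired test, mean difference > 0).  A one-tailed p equals half the
    two-tailed p whenever the observed effect lies in the hypothesised
    direction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if direction not in ("two-sided", "greater", "less"):
        raise ValueError(f"direction must be two-sided/greater/less, got {direction!r}")
    if test == "paired":
        if len(a) != len(b):
            raise ValueError(f"paired test needs equal lengths, got {len(a)} and {len(b)}")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        res = sps.ttest_rel(a, b, alternative=direction)
    elif test in ("independent", "welch"):
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 observations per group")
        res = sps.ttest_ind(a, b, equal_var=(test == "independent"), alternative=direction)
    else:
        raise ValueError(f"unknown test {test!r}; options: independent, welch, paired")
    def _shapiro(x):
        if len(x) < 3 or np.ptp(x) == 0:
            return (float("nan"), float("nan"))
        r = sps.shapiro(x)
        return (float(r.statistic), float(r.pvalue))

    shapiro = (_shapiro(a), _shapiro(b))
    f_stat, f_p = _variance_ratio_test(a, b)
    return GroupComparison(
        group_names=names,
        means=(float(a.mean()), float(b.mean())),
        sems=(_sem(a), _sem(b)),
        ns=(len(a), len(b)),
        test=test,
        direction=direction,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shapiro=shapiro,  # type: ignore[arg-type]
        f_statistic=f_stat,
        f_p_value=f_p,
    )
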