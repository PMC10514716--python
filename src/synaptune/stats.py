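"""Paired condition comparisons with a normality gate and family-wise
error control.

The decision tree mirrors common practice in slice-physiology and
imaging studies: paired differences are first screened with the
Lilliefors test for normality; if they pass, a Student paired t test is
used, otherwise the Wilcoxon signed-rank test.  Multiple comparisons are
controlled with the Holm-Bonferroni step-down procedure.  Balanced
within-subject two-factor designs (e.g. treatment x pulse position over
cells) use a two-way repeated-measures ANOVA, reporting the treatment
main effect as the headline statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ComparisonResult",
    "paired_compare",
    "rm_anova_two_way",
    "holm_bonferroni",
]


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    normality_p: float = float("nan")
    corrected_reject: bool | None = None
    degenerate: bool = False
    detail: dict = field(default_factory=dict)


def paired_compare(x, y, alpha: float = 0.05,
                   normality_alpha: float = 0.05) -> ComparisonResult:
    """Compare paired samples with a Lilliefors-gated t / signed-rank test.

    Normality is assessed on the paired differences (the quantity the
    paired test operates on).  With fewer than 4 pairs the Lilliefors
    test is unavailable and the t branch is used.  All-zero differences
    are degenerate: the result is flagged with statistic 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("paired comparison requires at least 3 pairs")
    d = x - y
    if np.all(d == 0):
        return ComparisonResult("paired_t", 0.0, 1.0, n, degenerate=True)
    if n >= 4 and np.std(d) > 0:
        _, norm_p = lilliefors(d, dist="norm", pvalmethod="table")
    else:
        norm_p = float("nan")
    if np.isnan(norm_p) or norm_p > normality_alpha:
        stat, p = sps.ttest_rel(x, y)
        name = "paired_t"
    else:
        nz = d[d != 0]
        exact = (
            n <= 25
            and nz.size == d.size  # exact distribution disallows zeros
            and np.unique(np.abs(nz)).size == nz.size  # ... and ties
        )
        res = sps.wilcoxon(x, y, correction=not exact,
                           method="exact" if exact else "approx")
        stat, p = res.statistic, res.pvalue
        name = "wilcoxon_signed_rank"
    return ComparisonResult(name, float(stat), float(p), n,
                            normality_p=float(norm_p),
                            detail={"alpha": alpha})


def rm_anova_two_way(values: np.ndarray) -> ComparisonResult:
    """Two-way repeated-measures ANOVA on a (subjects, treatments,
    positions) array.

    Requires a complete balanced within-subject design with at least two
    levels per factor.  The headline statistic is the treatment main
    effect; the full ANOVA table is available under
    ``result.detail["table"]``.
    """
    a = np.asarray(values, dtype=float)
    if a.ndim != 3:
        raise ValueError("values must be (subjects, treatments, positions)")
    n_sub, n_treat, n_pos = a.shape
    if n_sub < 2:
        raise ValueError("at least 2 subjects are required")
    if n_treat < 2 or n_pos < 2:
        raise ValueError("each within-subject factor needs at least 2 levels")
    if np.any(~np.isfinite(a)):
        raise ValueError("design contains missing cells")
    subs, treats, poss = np.meshgrid(
        np.arange(n_sub), np.arange(n_treat), np.arange(n_pos), indexing="ij"
    )
    df = pd.DataFrame({
        "subject": subs.ravel(),
        "treatment": treats.ravel(),
        "position": poss.ravel(),
        "value": a.ravel(),
    })
    table = AnovaRM(df, depvar="value", subject="subject",
                    within=["treatment", "position"]).fit().anova_table
    f = float(table.loc["treatment", "F Value"])
    p = float(table.loc["treatment", "Pr > F"])
    return ComparisonResult("rm_anova_treatment", f, p, n_sub,
                            detail={"table": table})


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down rejection decisions, in input order.

    Sort p ascending and reject p_(i) while p_(i) <= alpha / (m - i + 1),
    stopping at the first failure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):  # rank 0-based
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
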