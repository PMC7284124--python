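"""Subtype and diagnostic-group characterization statistics.

Two-sample comparisons (Welch t by default) with Benjamini-Hochberg FDR
applied within each variable family, Pearson chi-square on the
diagnosis-by-subtype contingency table, and one-way ANOVA with Tukey HSD
post-hoc comparisons for three-group contrasts.

The Benjamini-Hochberg adjustment is implemented here from the step-up
recursion (q_(i) = min over j >= i of p_(j) * m / j, clipped to 1), so
adjusted values agree bit-exactly with a hand recomputation; the test
statistics themselves come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult", "fdr_bh", "two_sample_tests",
    "chi_square_diagnosis", "anova_posthoc", "results_to_frame",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """Outcome of one variable's group comparison."""

    variable_id: str
    contrast: str
    statistic: float
    raw_p: float
    q_value: float = float("nan")
    significant: bool = False
    n_a: int = 0
    n_b: int = 0
    testable: bool = True


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable_id, "contrast": r.contrast,
        "statistic": r.statistic, "p": r.raw_p, "q": r.q_value,
        "significant": r.significant, "n_a": r.n_a, "n_b": r.n_b,
        "testable": r.testable,
    } for r in results])


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorted ascending, q_(i) = min_{j>=i} p_(j) * m / j, clipped to 1;
    the result is monotone nondecreasing along sorted raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def two_sample_tests(data: pd.DataFrame, group_a_ids: Sequence[str],
                     group_b_ids: Sequence[str], contrast: str = "A_vs_B",
                     equal_var: bool = False,
                     alpha: float = ALPHA) -> list[ComparisonResult]:
    """Per-variable two-tailed two-sample t tests with FDR over the call.

    ``data`` is subjects x variables (ROI features of one cortical
    parameter, or clinical scales); missing values are dropped pairwise
    per variable. A variable with fewer than 2 non-missing values in
    either group is marked untestable and excluded from the FDR family.
    Welch (unequal-variance) t is the default; ``equal_var=True`` selects
    the pooled-variance variant.
    """
    if len(group_a_ids) < 2 or len(group_b_ids) < 2:
        raise ValueError("each group needs at least 2 subjects")
    A = data.loc[list(group_a_ids)]
    B = data.loc[list(group_b_ids)]
    results: list[ComparisonResult] = []
    for var in data.columns:
        a = A[var].dropna().to_numpy(dtype=float)
        b = B[var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            results.append(ComparisonResult(str(var), contrast, float("nan"),
                                            float("nan"), testable=False,
                                            n_a=a.size, n_b=b.size))
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t, p = 0.0, 1.0        # degenerate: no variation, no difference
        else:
            t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        results.append(ComparisonResult(str(var), contrast, float(t), float(p),
                                        n_a=a.size, n_b=b.size))
    testable = [r for r in results if r.testable]
    if testable:
        q = fdr_bh([r.raw_p for r in testable])
        for r, qv in zip(testable, q):
            r.q_value = float(qv)
            r.significant = bool(qv < alpha)
    return results


def chi_square_diagnosis(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 diagnosis-by-subtype count table.

    No continuity correction (Yates' correction available via
    :func:`scipy.stats.chi2_contingency` directly if wanted); p from the
    chi-square distribution with 1 degree of freedom.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    assert dof == 1
    return float(stat), float(p)


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    significant: bool


def anova_posthoc(values: Sequence[float], group_labels: Sequence[str],
                  alpha: float = ALPHA
                  ) -> tuple[float, float, Optional[list[TukeyPair]]]:
    """One-way fixed-effects ANOVA; Tukey HSD pairwise post-hoc if significant.

    Requires at least 3 groups with at least 2 subjects each (use
    :func:`two_sample_tests` for two groups). Returns ``(F, p, pairs)``
    with ``pairs=None`` when the omnibus test is not significant.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    names = sorted(set(g.tolist()))
    if len(names) < 3:
        raise ValueError("need at least 3 groups (use two_sample_tests)")
    samples = [v[g == name] for name in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least 2 subjects")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return 0.0, 1.0, None      # identical constant groups
    F, p = sps.f_oneway(*samples)
    if not (p < alpha):
        return float(F), float(p), None
    res = sps.tukey_hsd(*samples)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pv = float(res.pvalue[i, j])
            pairs.append(TukeyPair(names[i], names[j],
                                   float(res.statistic[i, j]), pv, pv < alpha))
    return float(F), float(p), pairs
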