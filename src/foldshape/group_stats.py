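"""Group-comparison statistics for measurement tables.

Two-group contrasts use Welch's t-test (unequal variances,
Welch–Satterthwaite degrees of freedom).  Multi-group contrasts use a
one-way fixed-effects ANOVA with the experimental batch entered as an
additive blocking factor (Type-II sum of squares for the group factor), and,
when the ANOVA rejects, Tukey's Honest Significant Difference post-hoc test
on the ANOVA's error mean square.  The unit of analysis is the embryo: cell-
or side-level replicates are aggregated per embryo before testing.

Stars: *** p<0.005, ** p<0.01, * p<0.05.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import TestResult

__all__ = [
    "welch_t",
    "anova_with_batch",
    "tukey_hsd",
    "significance_stars",
    "aggregate_per_embryo",
    "run_group_comparison",
]


def welch_t(a, b) -> TestResult:
    """Welch's two-sample t-test (two-sided).

    t = (x̄₁ − x̄₂) / √(s₁²/n₁ + s₂²/n₂), df by Welch–Satterthwaite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    na, nb = len(a), len(b)
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a ** 2 / (na - 1) + se2b ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(p),
                      method="welch_t",
                      group_means={"a": float(a.mean()), "b": float(b.mean())},
                      group_sizes={"a": na, "b": nb})


def _dummies(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        return np.empty((len(labels), 0)), levels
    mat = np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])
    return mat, levels


def anova_with_batch(values, group, batch) -> TestResult:
    """One-way ANOVA for the group factor with batch as an additive block.

    Fits the fixed-effects linear model value ~ group + batch and tests the
    group factor with a Type-II F (extra sum of squares of group given
    batch).  Raises when the design is confounded (group aliased with
    batch).
    """
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    g_mat, g_levels = _dummies(group)
    b_mat, b_levels = _dummies(batch)
    if len(g_levels) < 2:
        raise ValueError("need at least 2 groups")
    n = len(y)
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept, g_mat, b_mat])
    expected_rank = 1 + (len(g_levels) - 1) + (len(b_levels) - 1)
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < expected_rank:
        raise ValueError(
            "confounded design: factors 'group' and 'batch' are aliased "
            "(group is constant within every batch pattern)")
    X_red = np.hstack([intercept, b_mat])
    sse_full = _ssr(y, X_full)
    sse_red = _ssr(y, X_red)
    df_group = len(g_levels) - 1
    df_error = n - rank_full
    if df_error <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_error = sse_full / df_error
    F = ((sse_red - sse_full) / df_group) / ms_error
    p = stats.f.sf(F, df_group, df_error)
    grp = np.asarray(group)
    means = {lv: float(y[grp == lv].mean()) for lv in g_levels}
    sizes = {lv: int((grp == lv).sum()) for lv in g_levels}
    return TestResult(statistic=float(F), df=float(df_group),
                      p_value=float(p), method="anova_with_batch",
                      group_means=means, group_sizes=sizes,
                      extra={"error_ms": float(ms_error),
                             "error_df": float(df_error),
                             "df_denominator": float(df_error)})


def _ssr(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def tukey_hsd(values, group, error_ms: float, error_df: float) -> list[TestResult]:
    """Tukey HSD pairwise comparisons using an external error mean square.

    For each pair, q = |x̄ᵢ − x̄ⱼ| / √(error_ms/2 · (1/nᵢ + 1/nⱼ)) (the
    Tukey–Kramer statistic), with the adjusted p from the studentized-range
    distribution with k groups and ``error_df`` error degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    grp = np.asarray(group)
    levels = sorted(pd.unique(grp).tolist())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups for Tukey HSD")
    results = []
    for a, b in combinations(levels, 2):
        ya, yb = y[grp == a], y[grp == b]
        na, nb = len(ya), len(yb)
        se = np.sqrt(error_ms / 2.0 * (1.0 / na + 1.0 / nb))
        q = abs(ya.mean() - yb.mean()) / se
        p = stats.studentized_range.sf(q, k, error_df)
        results.append(TestResult(
            statistic=float(q), df=float(error_df),
            p_value=float(np.clip(p, 0.0, 1.0)),
            method="tukey_hsd",
            group_means={str(a): float(ya.mean()), str(b): float(yb.mean())},
            group_sizes={str(a): na, str(b): nb},
            extra={"pair": (a, b), "k": k}))
    return results


def significance_stars(p: float) -> str:
    """Asterisk label: *** p<0.005, ** p<0.01, * p<0.05, '' otherwise."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def aggregate_per_embryo(table: pd.DataFrame, value_col: str = "value",
                         how: str = "mean") -> pd.DataFrame:
    """Collapse replicate rows (cells, sides) to one value per embryo.

    Expects columns embryo_id, group, batch (and ``value_col``); returns one
    row per embryo with the aggregated value.
    """
    required = {"embryo_id", "group", "batch", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    if not np.all(np.isfinite(table[value_col].to_numpy(dtype=float))):
        raise ValueError("values must be finite")
    grouped = table.groupby(["embryo_id", "group", "batch"], sort=True)
    agg = grouped[value_col].agg(how).reset_index()
    dup = agg.duplicated("embryo_id", keep=False)
    if dup.any():
        raise ValueError("an embryo appears in more than one group/batch")
    return agg


def run_group_comparison(table: pd.DataFrame, value_col: str = "value",
                         gate_p: float = 0.05, aggregate: str = "mean"):
    """Embryo-level omnibus test plus (gated) post-hoc contrasts.

    Aggregates replicates per embryo, runs the batch-blocked ANOVA and, when
    its p-value is below ``gate_p``, Tukey HSD on the ANOVA error term.
    Returns (anova TestResult, list of pairwise TestResults — empty when the
    gate is not passed).
    """
    agg = aggregate_per_embryo(table, value_col, aggregate)
    anova = anova_with_batch(agg[value_col], agg["group"], agg["batch"])
    pairwise = []
    if anova.p_value < gate_p:
        pairwise = tukey_hsd(agg[value_col], agg["group"],
                             anova.extra["error_ms"], anova.extra["error_df"])
    return anova, pairwise
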