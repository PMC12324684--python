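"""Replicate-aware statistics and superplot tables.

Statistics follow the superplot convention: hypothesis tests run on the
means of experimental replicates, never on pooled per-cell values, so the
test n is the number of replicates. Available tests: Welch's t,
Student's t, paired t, one-sample t, one-way ANOVA, and the
Wilcoxon/Mann-Whitney rank tests as the non-normal fallback; ``auto``
chooses Welch vs rank test by a Shapiro–Wilk normality check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SHAPIRO_ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    fold_change: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float


def replicate_means(records: pd.DataFrame,
                    value_col: str,
                    condition_col: str = "condition",
                    replicate_col: str = "replicate") -> pd.DataFrame:
    """Collapse per-cell values to one mean per (condition, replicate)."""
    out = (records.groupby([condition_col, replicate_col], sort=True)[value_col]
           .agg(["mean", "count"]).reset_index())
    return out.rename(columns={"mean": "replicate_mean", "count": "n_cells"})


def _rank_test(a: np.ndarray, b: np.ndarray, paired: bool) -> tuple[float, float]:
    if np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0  # identical samples carry no evidence either way
    if paired:
        res = sps.wilcoxon(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def replicate_test(a, b, test: str = "welch", paired: bool = False) -> TestResult:
    """Two-group test on replicate means.

    ``a`` and ``b`` are sequences of replicate means (>= 2 each).
    ``test``: ``welch`` (default), ``student``, ``rank`` (Wilcoxon signed
    rank if paired, Mann-Whitney otherwise) or ``auto`` (Welch, falling
    back to the rank test when Shapiro–Wilk rejects normality in either
    group at alpha 0.05). The report includes the fold change of group
    means (b relative to a).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two-sample tests need >= 2 replicates per group")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = mean_b / mean_a if mean_a != 0 else np.inf

    chosen = test
    if test == "auto":
        normal = True
        for grp in (a, b):
            if len(grp) >= 3 and np.ptp(grp) > 0:
                if sps.shapiro(grp).pvalue < SHAPIRO_ALPHA:
                    normal = False
        chosen = "welch" if normal else "rank"

    if chosen == "welch":
        res = sps.ttest_rel(a, b) if paired else sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif chosen == "student":
        res = sps.ttest_rel(a, b) if paired else sps.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    elif chosen == "rank":
        stat, p = _rank_test(a, b, paired)
    else:
        raise ValueError(f"unknown test {test!r}")
    if np.isnan(p):  # degenerate zero-variance identical groups
        stat, p = 0.0, 1.0
    return TestResult(test=chosen, statistic=stat, p_value=p, fold_change=float(fold),
                      n_a=len(a), n_b=len(b), mean_a=mean_a, mean_b=mean_b)


def one_sample_test(values, popmean: float = 1.0) -> TestResult:
    """One-sample t test of replicate means against a reference value."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("one-sample test needs >= 2 replicates")
    res = sps.ttest_1samp(values, popmean)
    mean = float(values.mean())
    return TestResult(test="one-sample-t", statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      fold_change=mean / popmean if popmean else np.inf,
                      n_a=len(values), n_b=0, mean_a=mean, mean_b=popmean)


def anova(*groups) -> tuple[float, float]:
    """One-way ANOVA on replicate means across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    res = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def welch_pvalues_vectorized(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch p-values for many simulations at once.

    ``a`` and ``b`` have shape (n_sim, n_rep); one p-value per row. Used
    for calibration studies where calling scipy per simulation would
    dominate the runtime.
    """
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1) / na
    vb = b.var(axis=1, ddof=1) / nb
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    return 2.0 * sps.t.sf(np.abs(t), df)


def superplot_table(records: pd.DataFrame,
                    value_col: str,
                    condition_col: str = "condition",
                    replicate_col: str = "replicate") -> pd.DataFrame:
    """Long-format table for superplots: per-cell values + replicate means.

    Emits one row per cell (``row_type='value'``) and one per replicate
    (``row_type='replicate_mean'``) with a ``style_key`` so plotting code
    can match each replicate's mean marker to its cells. No statistics.
    """
    if records.empty:
        return pd.DataFrame(columns=[condition_col, replicate_col, value_col,
                                     "row_type", "style_key"])
    for col in (condition_col, replicate_col, value_col):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    values = records[[condition_col, replicate_col, value_col]].copy()
    values["row_type"] = "value"
    means = (records.groupby([condition_col, replicate_col], sort=True)[value_col]
             .mean().reset_index())
    means["row_type"] = "replicate_mean"
    out = pd.concat([values, means], ignore_index=True)
    out["style_key"] = out[replicate_col].astype(str)
    return out
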