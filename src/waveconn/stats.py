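"""Comparison battery for graph metrics across wavelet choices.

Quantifies how the wavelet method (DWT vs MODWT), filter family and
filter length change graph-metric estimates and group differences: a
length-variation statistic, paired and pooled two-sample t-tests, an
exact sign test, Bonferroni family-wise correction, one-way
repeated-measures ANOVA with filter length as the within-subject
factor, and -log10(p) sensitivity surfaces for control-vs-patient
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from waveconn.graphs import METRIC_NAMES

__all__ = [
    "TestResult",
    "variation_over_lengths",
    "paired_t_test",
    "two_sample_t_test",
    "sign_test",
    "rm_anova_length",
    "rm_anova_from_wide",
    "familywise_correct",
    "sensitivity_surface",
    "variation_table",
]

#: Columns that key a CohortResultTable row.
TABLE_KEYS = ["subject_id", "group", "method", "family", "length", "scale"]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    df: int | tuple[int, int]
    p_value: float
    test_name: str
    degenerate: bool = False


def variation_over_lengths(values_by_length) -> float:
    """Total absolute change of a metric across consecutive filter lengths.

    ``sum_k |v[k+1] - v[k]|`` for values ordered by ascending length; a
    small value means the estimate moves smoothly with filter length.
    """
    v = np.asarray(values_by_length, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least two lengths, ordered ascending")
    return float(np.abs(np.diff(v)).sum())


def paired_t_test(a, b) -> TestResult:
    """Classical paired t-test (df = n - 1), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length n >= 2")
    diff = a - b
    n = diff.size
    if np.allclose(diff.std(ddof=1), 0.0):
        return TestResult(float("nan"), n - 1, float("nan"), "paired_t",
                          degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return TestResult(float(t), n - 1, float(p), "paired_t")


def two_sample_t_test(a, b) -> TestResult:
    """Pooled-variance two-sample t-test (df = n_a + n_b - 2), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return TestResult(0.0, df, 1.0, "two_sample_t", degenerate=True)
        return TestResult(float("nan"), df, float("nan"), "two_sample_t",
                          degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), df, float(p), "two_sample_t")


def sign_test(a, b) -> TestResult:
    """Exact two-sided sign test that the paired-difference median is zero.

    Zero differences are dropped; the statistic is the number of
    positive differences among the m non-zero ones, referred to a
    Binomial(m, 1/2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nonzero = diff[diff != 0.0]
    m = nonzero.size
    if m == 0:
        return TestResult(float("nan"), 0, float("nan"), "sign",
                          degenerate=True)
    n_pos = int((nonzero > 0).sum())
    p = sps.binomtest(n_pos, m, 0.5, alternative="two-sided").pvalue
    return TestResult(float(n_pos), m, float(min(p, 1.0)), "sign")


def rm_anova_from_wide(data: np.ndarray) -> TestResult:
    """One-way repeated-measures ANOVA on a (subjects x conditions) array.

    The condition (here: wavelet filter length) is the within-subject
    factor; F is MS_condition / MS_error with df (k-1, (k-1)(n-1))
    after removing the subject main effect.  No sphericity correction
    is applied.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("expect a subjects x conditions array")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return TestResult(float("nan"), (df_cond, df_err), float("nan"),
                          "rm_anova", degenerate=True)
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df_cond, df_err))
    return TestResult(float(F), (df_cond, df_err), p, "rm_anova")


def rm_anova_length(table: pd.DataFrame, metric: str, family: str,
                    scale: int, method: str = "MODWT",
                    group: str | None = "control") -> TestResult:
    """Repeated-measures ANOVA of one metric over filter lengths.

    Pivots the cohort result table to a complete subject-by-length grid
    for the given family/scale/method (controls only by default, as in
    a healthy-reference design) and tests the within-subject length
    effect.
    """
    sub = table[(table["family"] == family) & (table["scale"] == scale)
                & (table["method"] == method)]
    if group is not None:
        sub = sub[sub["group"] == group]
    wide = sub.pivot_table(index="subject_id", columns="length",
                           values=metric)
    if wide.isna().any().any():
        missing = [
            (str(i), int(c))
            for i, c in zip(*np.nonzero(wide.isna().values))
        ]
        raise ValueError(f"incomplete subject x length grid; missing {missing}")
    return rm_anova_from_wide(wide.values)


def familywise_correct(p_values, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni family-wise correction: significant iff p <= alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p <= alpha / p.size


def variation_table(table: pd.DataFrame, metric: str,
                    scale: int | None = None) -> pd.DataFrame:
    """Per-subject length-variation statistic for each cell of the sweep.

    Returns one row per (subject_id, group, method, family[, scale])
    with the variation statistic of ``metric`` over ascending filter
    lengths.
    """
    keys = ["subject_id", "group", "method", "family"]
    sub = table
    if scale is not None:
        sub = table[table["scale"] == scale]
    else:
        keys = keys + ["scale"]
    rows = []
    for key, grp in sub.groupby(keys, sort=True):
        ordered = grp.sort_values("length")[metric].to_numpy()
        if ordered.size < 2:  # family swept at a single length
            continue
        rows.append(dict(zip(keys, key)) | {
            "metric": metric,
            "variation": variation_over_lengths(ordered),
        })
    return pd.DataFrame(rows)


def sensitivity_surface(table: pd.DataFrame, scale: int,
                        method: str = "MODWT",
                        metrics=METRIC_NAMES) -> pd.DataFrame:
    """-log10(p) of control-vs-patient two-sample t-tests per sweep cell.

    One row per (family, length, metric); larger values indicate a
    stronger group difference.
    """
    sub = table[(table["scale"] == scale) & (table["method"] == method)]
    rows = []
    for (family, length), grp in sub.groupby(["family", "length"], sort=True):
        ctrl = grp[grp["group"] == "control"]
        pat = grp[grp["group"] == "patient"]
        if ctrl.empty or pat.empty:
            raise ValueError("both groups must be present")
        for metric in metrics:
            res = two_sample_t_test(ctrl[metric].to_numpy(),
                                    pat[metric].to_numpy())
            rows.append({
                "family": family, "length": int(length), "metric": metric,
                "t": res.statistic,
                "neg_log10_p": float(-np.log10(res.p_value))
                if np.isfinite(res.p_value) and res.p_value > 0 else float("inf"),
            })
    return pd.DataFrame(rows)
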