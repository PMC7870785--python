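"""Cohort summary statistics: per-group MoM distributions and comparisons.

Mirrors the descriptive layer of a screening study: per-group median MoM,
mean and sample SD of log10 MoM, pairwise Pearson correlations on the
log10 scale, and Mann-Whitney U comparisons between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mom import median_low
from .params import MARKERS, GroupParams


@dataclass
class TestResult:
    """A two-sample Mann-Whitney comparison for one marker."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int
    group_a: str = "a"
    group_b: str = "b"
    marker: str | None = None


def summarize_group(
    mom: pd.DataFrame,
    group: str,
    markers: tuple[str, ...] = MARKERS,
) -> GroupParams:
    """Estimate GroupParams from a MoM table of one group.

    Mean and SD use the arithmetic mean and the n-1 denominator on
    log10 MoM; median MoM uses the lower-middle sample median;
    correlations are Pearson on log10 MoM.  A zero-variance marker gets
    NaN in its correlation row/column rather than an error.
    """
    n = len(mom)
    if n < 2:
        raise ValueError(f"need at least 2 subjects to summarize, got {n}")
    log_cols = [f"{m}_log10_mom" for m in markers]
    x = mom[log_cols].to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    k = len(markers)
    corr = np.full((k, k), np.nan)
    np.fill_diagonal(corr, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        full = np.corrcoef(x, rowvar=False)
    for i in range(k):
        for j in range(k):
            if i != j and sds[i] > 0 and sds[j] > 0:
                corr[i, j] = full[i, j]
    medians = np.array(
        [median_low(mom[f"{m}_mom"].to_numpy(dtype=float)) for m in markers]
    )
    return GroupParams(
        group=group,
        mean_log10_mom=means,
        sd_log10_mom=sds,
        correlation=corr,
        median_mom=medians,
        n=n,
    )


def mann_whitney(
    values_a,
    values_b,
    group_a: str = "a",
    group_b: str = "b",
    marker: str | None = None,
    exact_limit: int = 10_000,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when ``n_a * n_b`` is small and the data are
    tie-free, otherwise the normal approximation with midrank tie
    correction and continuity correction.  The reported U counts wins of
    sample *a* over sample *b* (plus half-ties).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= exact_limit and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=a.size,
        n_b=b.size,
        group_a=group_a,
        group_b=group_b,
        marker=marker,
    )


def pairwise_correlations(
    mom: pd.DataFrame,
    markers: tuple[str, ...] = MARKERS,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations of log10 MoM with two-sided p-values.

    Returns ``(r, p)`` matrices; p-values use the t distribution with
    n-2 degrees of freedom.  Zero-variance markers yield NaN rows.
    """
    n = len(mom)
    if n < 3:
        raise ValueError("need at least 3 subjects for correlations")
    k = len(markers)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    cols = [mom[f"{m}_log10_mom"].to_numpy(dtype=float) for m in markers]
    for i in range(k):
        for j in range(i + 1, k):
            if np.std(cols[i]) == 0 or np.std(cols[j]) == 0:
                continue
            res = sps.pearsonr(cols[i], cols[j])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return r, p


def group_summary_table(
    cohort: pd.DataFrame,
    mom: pd.DataFrame,
    markers: tuple[str, ...] = MARKERS,
) -> pd.DataFrame:
    """Reference-table style summary: one row block per statistic.

    Rows are ``median_{marker}_mom``, ``mean_log10_{marker}_mom``,
    ``sd_log10_{marker}_mom`` and the correlation block; one column per
    group present in the cohort.
    """
    groups = list(dict.fromkeys(cohort["group"]))
    rows: dict[str, dict[str, float]] = {}
    for group in groups:
        mask = (cohort["group"] == group).to_numpy()
        sub = mom.loc[mask]
        if len(sub) < 2:
            continue
        gp = summarize_group(sub, group, markers)
        col: dict[str, float] = {}
        for i, m in enumerate(markers):
            col[f"median_{m}_mom"] = gp.median_mom[i]
            col[f"mean_log10_{m}_mom"] = gp.mean_log10_mom[i]
            col[f"sd_log10_{m}_mom"] = gp.sd_log10_mom[i]
        for i in range(len(markers)):
            for j in range(i + 1, len(markers)):
                col[f"corr_{markers[i]}_vs_{markers[j]}"] = gp.correlation[i, j]
        col["n"] = gp.n
        for key, value in col.items():
            rows.setdefault(key, {})[group] = value
    return pd.DataFrame(rows).T[groups]
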