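"""Cohort-level statistics: prevalence tables, chi-square with Bonferroni
post hoc, Kruskal-Wallis with Dunn post hoc, and intraclass correlation.

The chi-square omnibus is Pearson's statistic without continuity correction
(a flag enables Yates' correction for 2x2 tables).  Pairwise post hoc tests
are 2xk chi-square tests between pairs of rows with the raw p value
multiplied by the number of comparisons (Bonferroni), capped at 1.

The ICC defaults to the two-way random-effects, single-measure,
absolute-agreement form (ICC(2,1)); a ``consistency`` override gives
ICC(3,1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .classification import DeformityLocation, Severity, classify_location, classify_severity
from .geometry import KneeAlignment

__all__ = [
    "prevalence_by_severity",
    "chi_square_independence",
    "pairwise_posthoc",
    "kruskal_wallis_posthoc",
    "icc",
    "ICCResult",
]


def prevalence_by_severity(cohort: Iterable[KneeAlignment]) -> pd.DataFrame:
    """Severity x deformity-location counts (shape of the prevalence tables)."""
    severities = [s.value for s in Severity]
    locations = [loc.value for loc in DeformityLocation]
    table = pd.DataFrame(0, index=severities, columns=locations, dtype=int)
    for knee in cohort:
        sev = classify_severity(knee.mFTA).value
        loc = classify_location(knee).value
        table.loc[sev, loc] += 1
    table.index.name = "severity"
    table.columns.name = "location"
    return table


def _as_counts(table) -> np.ndarray:
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (counts < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return counts


def chi_square_independence(
    table, *, continuity_correction: bool = False
) -> Tuple[float, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns ``(statistic, p_value)``.  Raises if any expected count is zero,
    naming the offending cell.
    """
    counts = _as_counts(table)
    # Drop all-zero rows/columns only if the caller passed them explicitly?
    # No: a zero margin makes an expected cell zero, which we must reject.
    row_tot = counts.sum(axis=1, keepdims=True)
    col_tot = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    if total == 0:
        raise ValueError("contingency table is empty")
    expected = row_tot @ col_tot / total
    zero = np.argwhere(expected == 0)
    if zero.size:
        r, c = zero[0]
        raise ValueError(f"expected count is zero in cell (row {r}, column {c})")
    stat, p, _, _ = stats.chi2_contingency(counts, correction=continuity_correction)
    return float(stat), float(p)


def pairwise_posthoc(
    table, *, adjust: str = "bonferroni", continuity_correction: bool = False
) -> Dict[Tuple[object, object], float]:
    """All pairwise 2xk chi-square tests between rows, Bonferroni-adjusted.

    Requires at least 3 rows (with 2 groups the omnibus already is the
    pairwise test).  Returns a mapping of row-label pairs to adjusted p.
    """
    if adjust != "bonferroni":
        raise ValueError(f"unsupported adjustment {adjust!r}")
    df = pd.DataFrame(table)
    if df.shape[0] < 3:
        raise ValueError("post hoc tests require at least 3 groups (rows)")
    pairs = list(itertools.combinations(df.index, 2))
    m = len(pairs)
    out: Dict[Tuple[object, object], float] = {}
    for a, b in pairs:
        sub = df.loc[[a, b]]
        sub = sub.loc[:, sub.sum(axis=0) > 0]  # drop empty columns for the 2xk test
        _, p = chi_square_independence(sub, continuity_correction=continuity_correction)
        out[(a, b)] = min(1.0, m * p)
    return out


def kruskal_wallis_posthoc(
    groups: Mapping[object, Sequence[float]],
) -> Tuple[float, float, Dict[Tuple[object, object], float]]:
    """Kruskal-Wallis omnibus plus Dunn pairwise z-tests (Bonferroni).

    Returns ``(H, omnibus_p, {pair: adjusted_p})``.  Groups with fewer than
    two observations are excluded from the post hoc comparisons.
    """
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need at least 2 non-empty groups")
    h_stat, omnibus_p = stats.kruskal(*samples)

    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term for the Dunn variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))

    mean_ranks: Dict[object, float] = {}
    start = 0
    for label, s in zip(labels, samples):
        mean_ranks[label] = float(ranks[start : start + len(s)].mean())
        start += len(s)

    eligible = [k for k, s in zip(labels, samples) if len(s) >= 2]
    pairs = list(itertools.combinations(eligible, 2))
    m = len(pairs)
    adjusted: Dict[Tuple[object, object], float] = {}
    for a, b in pairs:
        na, nb = len(groups[a]), len(groups[b])
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        adjusted[(a, b)] = min(1.0, m * p)
    return float(h_stat), float(omnibus_p), adjusted


@dataclass(frozen=True)
class ICCResult:
    value: float
    model: str
    n_subjects: int
    n_raters: int


def icc(ratings, model: str = "absolute_agreement") -> ICCResult:
    """Single-measure intraclass correlation from the two-way ANOVA table.

    ``ratings`` is a subjects x raters matrix with no missing cells.
    ``model='absolute_agreement'`` gives ICC(2,1); ``model='consistency'``
    gives ICC(3,1).

    Raises
    ------
    ValueError
        For fewer than 2 subjects/raters, missing cells, or zero total
        variance (the ICC is undefined).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters matrix, both >= 2")
    if not np.isfinite(x).all():
        raise ValueError("ratings must have no missing cells")
    n, k = x.shape
    grand = x.mean()
    subject_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)

    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total variance: ICC is undefined")
    ss_rows = k * ((subject_means - grand) ** 2).sum()
    ss_cols = n * ((rater_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)  # between-subjects
    msc = ss_cols / (k - 1)  # between-raters
    mse = ss_err / ((n - 1) * (k - 1))  # residual

    if model == "absolute_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom
    elif model == "consistency":
        value = (msr - mse) / (msr + (k - 1) * mse)
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    return ICCResult(value=float(value), model=model, n_subjects=n, n_raters=k)
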