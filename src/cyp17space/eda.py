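"""Per-group descriptor summaries and two-group nonparametric comparison.

Summaries report min/max/median/mean plus bias-corrected sample skewness and
excess kurtosis, with a Shapiro-Wilk normality p-value for 3 <= n <= 5000.
Group comparison is the two-sided Mann-Whitney U test: exact by full
enumeration of group assignments when both samples have n <= 8 (ties are
handled naturally, since assignments of the pooled *values* are enumerated),
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 8


@dataclass(frozen=True)
class DescriptorSummary:
    group: str
    n: int
    min: float
    max: float
    median: float
    mean: float
    skewness: float  # NaN marks "undefined" (n < 3 or zero variance)
    kurtosis: float  # excess convention unless raw requested; NaN as above
    normality_p: float  # NaN outside the 3..5000 Shapiro range


def summarize(values: Sequence[float], group: str = "", raw_kurtosis: bool = False) -> DescriptorSummary:
    """Moment summary of one descriptor within one group.

    Skewness is the bias-corrected sample skewness; kurtosis is excess
    kurtosis by default (``raw_kurtosis=True`` adds back 3). Degenerate
    inputs (n < 3 or zero variance) report NaN, never a silent 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("summarize requires at least one value")
    degenerate = x.size < 3 or np.ptp(x) == 0
    if degenerate:
        skew = kurt = math.nan
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, bias=False, fisher=True))
        if raw_kurtosis:
            kurt += 3.0
    if 3 <= x.size <= 5000 and np.ptp(x) > 0:
        normality_p = float(stats.shapiro(x).pvalue)
    else:
        normality_p = math.nan
    return DescriptorSummary(
        group=group,
        n=int(x.size),
        min=float(x.min()),
        max=float(x.max()),
        median=float(np.median(x)),
        mean=float(x.mean()),
        skewness=skew,
        kurtosis=kurt,
        normality_p=normality_p,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample ``a`` (ties count one half)."""
    u = 0.0
    for x in a:
        u += np.sum(x > b) + 0.5 * np.sum(x == b)
    return float(u)


def _exact_mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by enumerating all C(na+nb, na) group assignments.

    Under exchangeability the U distribution is symmetric about na*nb/2 even
    with ties, so the two-sided p is twice the smaller tail (capped at 1).
    """
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    u_obs = _u_statistic(a, b)
    le = ge = total = 0
    idx = np.arange(n)
    for comb in combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return u_obs, p


def compare_groups(a: Sequence[float], b: Sequence[float], method: str = "auto") -> dict:
    """Two-sided Mann-Whitney U comparison of two samples.

    ``method``: ``auto`` (exact when both n <= 8, else asymptotic),
    ``exact`` or ``asymptotic``. Returns ``{u_statistic, p_value, method}``
    where ``u_statistic`` is U for the first sample.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if (x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N) else "asymptotic"
    if method == "exact":
        u, p = _exact_mannwhitney(x, y)
    elif method == "asymptotic":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"u_statistic": u, "p_value": p, "method": method}


def eda_table(
    descriptor_df: pd.DataFrame,
    groups: pd.Series,
    raw_kurtosis: bool = False,
) -> pd.DataFrame:
    """Descriptor x group summary table with between-group Mann-Whitney p.

    ``groups`` is a per-compound label series aligned with
    ``descriptor_df``'s index; the p-value column compares the first two
    group labels (sorted) for each descriptor.
    """
    labels = sorted(groups.dropna().unique())
    rows = []
    for desc in descriptor_df.columns:
        for label in labels:
            vals = descriptor_df.loc[groups == label, desc].dropna()
            s = summarize(vals.to_numpy(), group=str(label), raw_kurtosis=raw_kurtosis)
            row = {"descriptor": desc, **s.__dict__}
            if len(labels) >= 2:
                va = descriptor_df.loc[groups == labels[0], desc].dropna().to_numpy()
                vb = descriptor_df.loc[groups == labels[1], desc].dropna().to_numpy()
                row["mannwhitney_p"] = compare_groups(va, vb)["p_value"]
            rows.append(row)
    return pd.DataFrame(rows)
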