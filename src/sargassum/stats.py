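"""Period-change tests and monthly climatology box statistics.

Whether the annual biomass of two eras differs is assessed the classic
two-stage way: a two-sample variance-ratio F-test decides whether the
two populations can be treated as homoscedastic, and the two-sample
t-test is then run in its pooled-variance flavour when they can and in
its Welch (unequal-variance) flavour when they cannot.  Both flavours
are also callable directly so either convention can be reproduced.

Seasonality shifts are described with per-calendar-month box statistics:
quartiles by linear interpolation, Tukey whiskers at the most extreme
points within 1.5 interquartile ranges of the quartiles, and everything
beyond flagged as an outlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class FTestResult:
    f_stat: float
    p_value: float
    equal_variances: bool
    df_num: int
    df_den: int


@dataclass
class PeriodComparison:
    """Two annual-biomass samples and their F/t test results."""

    sample_a: np.ndarray
    sample_b: np.ndarray
    f_stat: float
    f_p: float
    variances_equal: bool
    t_stat: float
    t_p: float
    t_flavour: str  # 'pooled' | 'welch'
    alpha: float = 0.05


@dataclass
class MonthBox:
    month: int
    n: int
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def f_test_equal_variance(x, y, alpha: float = 0.05) -> FTestResult:
    """Two-sample variance-ratio F-test.

    The statistic is the larger sample variance over the smaller (so
    F >= 1) with the corresponding degrees of freedom; the two-sided
    p-value doubles the upper tail (capped at 1).  ``equal_variances``
    is True when p >= alpha.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    if vx >= vy:
        num_v, den_v, dfn, dfd = vx, vy, x.size - 1, y.size - 1
    else:
        num_v, den_v, dfn, dfd = vy, vx, y.size - 1, x.size - 1
    if den_v == 0:
        f = np.inf
        p = 0.0
    else:
        f = num_v / den_v
        p = min(1.0, 2.0 * sps.f.sf(f, dfn, dfd))
    return FTestResult(f_stat=float(f), p_value=float(p),
                       equal_variances=bool(p >= alpha), df_num=dfn, df_den=dfd)


def two_sample_t(x, y, flavour: str = "auto", alpha: float = 0.05) -> PeriodComparison:
    """Two-sample t-test with F-test-driven flavour selection.

    ``flavour='auto'`` runs the variance-ratio F-test first and uses the
    pooled-variance statistic when variances are judged equal at
    ``alpha``, Welch's statistic otherwise.  ``'pooled'``/``'welch'``
    force a flavour (the F-test is still reported).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if flavour not in ("auto", "pooled", "welch"):
        raise ValueError(f"unknown flavour {flavour!r}")
    ft = f_test_equal_variance(x, y, alpha=alpha)
    if flavour == "auto":
        flavour = "pooled" if ft.equal_variances else "welch"
    res = sps.ttest_ind(x, y, equal_var=(flavour == "pooled"))
    return PeriodComparison(
        sample_a=x, sample_b=y,
        f_stat=ft.f_stat, f_p=ft.p_value, variances_equal=ft.equal_variances,
        t_stat=float(res.statistic), t_p=float(res.pvalue),
        t_flavour=flavour, alpha=alpha,
    )


def climatology_box(series, years: set[int] | None = None) -> list[MonthBox]:
    """Per-calendar-month box statistics of a monthly biomass series.

    ``series`` is a BiomassSeries or a DataFrame with ``year``,
    ``month`` and ``biomass_t`` columns.  Quartiles use linear
    interpolation between order statistics; whiskers sit at the most
    extreme data points within [Q1 - 1.5 IQR, Q3 + 1.5 IQR]; values
    outside are outliers.  Months with no data yield no record.
    """
    table = getattr(series, "table", series)
    if years is not None:
        table = table[table["year"].isin(years)]
    boxes: list[MonthBox] = []
    for month in range(1, 13):
        vals = np.sort(table.loc[table["month"] == month, "biomass_t"].to_numpy(float))
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        boxes.append(MonthBox(
            month=month, n=vals.size, q1=float(q1), median=float(med), q3=float(q3),
            whisker_low=float(inside.min()), whisker_high=float(inside.max()),
            outliers=vals[(vals < lo_fence) | (vals > hi_fence)],
        ))
    return boxes


def comparison_report(cmp: PeriodComparison) -> dict:
    """JSON-ready summary of a period comparison."""
    return {
        "f_stat": cmp.f_stat, "f_p": cmp.f_p,
        "t_stat": cmp.t_stat, "t_p": cmp.t_p,
        "flavour": cmp.t_flavour, "alpha": cmp.alpha,
        "n_a": int(cmp.sample_a.size), "n_b": int(cmp.sample_b.size),
        "mean_a": float(cmp.sample_a.mean()), "mean_b": float(cmp.sample_b.mean()),
        "sd_a": float(cmp.sample_a.std(ddof=1)), "sd_b": float(cmp.sample_b.std(ddof=1)),
    }


def select_period(series_table: pd.DataFrame, years: range) -> np.ndarray:
    """Annual-mean biomass values for the ecological years in ``years``."""
    annual = series_table.groupby("ecological_year")["biomass_t"].mean()
    return annual[annual.index.isin(list(years))].to_numpy(float)
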