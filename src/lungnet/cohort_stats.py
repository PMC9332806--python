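"""Lot-level aggregation and two-sample separation statistics.

Per-sample network metrics (degree sum, mean degree, maximum degree) are
collected across a cohort of normal and DILD-affected samples and compared
with a two-sample t-test assuming unequal variances (Welch), the standard
spreadsheet-style analysis: sample variances use the n−1 denominator,
degrees of freedom follow Welch–Satterthwaite, and one- and two-tailed
p-values and critical values at α are reported. A complementary
scale-free comparison expresses each group's standard deviation as a
percentage of the two SDs' sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .degree_analysis import NetworkMetrics
from .errors import DomainError, InsufficientDataError, UndefinedStatisticError

NORMAL = "normal"
DILD = "dild"

METRIC_NAMES = ("total_count", "average_count", "max_degree")


@dataclass(frozen=True)
class CohortRecord:
    """Metrics of one (sample, band) pair with its group label."""

    sample_id: str
    group: str  # "normal" | "dild"
    band_name: str
    metrics: NetworkMetrics
    subclass: str | None = None  # e.g. UIP, OP, HP

    def __post_init__(self) -> None:
        if self.group not in (NORMAL, DILD):
            raise DomainError(f"group must be '{NORMAL}' or '{DILD}'")


@dataclass(frozen=True)
class WelchResult:
    """Summary of a Welch two-sample test, mirroring the spreadsheet layout.

    ``df`` is the Welch–Satterthwaite value floored to an integer for
    reporting; p-values and critical values are computed from the unrounded
    ``df_exact``.
    """

    mean1: float
    mean2: float
    var1: float
    var2: float
    n1: int
    n2: int
    t_stat: float
    df: int
    df_exact: float
    p_one_tail: float
    p_two_tail: float
    t_crit_one_tail: float
    t_crit_two_tail: float
    alpha: float = 0.05

    def as_series(self) -> pd.Series:
        """Row-labelled summary in the familiar spreadsheet order."""
        return pd.Series(
            {
                "Mean 1": self.mean1,
                "Mean 2": self.mean2,
                "Variance 1": self.var1,
                "Variance 2": self.var2,
                "Observations 1": self.n1,
                "Observations 2": self.n2,
                "Hypothesized Mean Difference": 0.0,
                "df": self.df,
                "t Stat": self.t_stat,
                "P(T<=t) one-tail": self.p_one_tail,
                "t Critical one-tail": self.t_crit_one_tail,
                "P(T<=t) two-tail": self.p_two_tail,
                "t Critical two-tail": self.t_crit_two_tail,
            }
        )


def t_critical(df: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Upper critical value of Student's t.

    One-tailed: the (1−α) quantile; two-tailed: the (1−α/2) quantile.
    """
    if df <= 0:
        raise DomainError("df must be positive")
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise DomainError("tails must be 1 or 2")
    q = alpha if tails == 1 else alpha / 2
    return float(stats.t.ppf(1 - q, df))


def welch_from_summaries(
    mean1: float,
    var1: float,
    n1: int,
    mean2: float,
    var2: float,
    n2: int,
    alpha: float = 0.05,
) -> WelchResult:
    """Welch's t-test from group summaries (n−1 sample variances).

    t = (m1 − m2) / sqrt(v1/n1 + v2/n2); df by Welch–Satterthwaite:
    df = (v1/n1 + v2/n2)² / [ (v1/n1)²/(n1−1) + (v2/n2)²/(n2−1) ].
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    if var1 < 0 or var2 < 0:
        raise DomainError("variances must be non-negative")
    if var1 == 0 and var2 == 0:
        raise UndefinedStatisticError("both sample variances are zero")

    se1, se2 = var1 / n1, var2 / n2
    se = math.sqrt(se1 + se2)
    t_stat = (mean1 - mean2) / se
    df_exact = (se1 + se2) ** 2 / (
        se1**2 / (n1 - 1) + se2**2 / (n2 - 1)
    )
    p_one = float(stats.t.sf(abs(t_stat), df_exact))
    return WelchResult(
        mean1=mean1,
        mean2=mean2,
        var1=var1,
        var2=var2,
        n1=n1,
        n2=n2,
        t_stat=t_stat,
        df=math.floor(df_exact),
        df_exact=df_exact,
        p_one_tail=p_one,
        p_two_tail=2 * p_one,
        t_crit_one_tail=t_critical(df_exact, alpha, tails=1),
        t_crit_two_tail=t_critical(df_exact, alpha, tails=2),
        alpha=alpha,
    )


def welch_from_samples(x1: Iterable[float], x2: Iterable[float],
                       alpha: float = 0.05) -> WelchResult:
    """Welch's t-test from raw observations."""
    a = np.asarray(list(x1), dtype=float)
    b = np.asarray(list(x2), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    return welch_from_summaries(
        float(a.mean()), float(a.var(ddof=1)), a.size,
        float(b.mean()), float(b.var(ddof=1)), b.size,
        alpha=alpha,
    )


def records_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Long-format cohort table: one row per (sample, band)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "subclass": [r.subclass for r in records],
            "band": [r.band_name for r in records],
            "total_count": [r.metrics.total_count for r in records],
            "average_count": [r.metrics.average_count for r in records],
            "max_degree": [r.metrics.max_degree for r in records],
        }
    )


def _metric_values(records: Sequence[CohortRecord], metric: str,
                   group: str, band: str | None) -> np.ndarray:
    if metric not in METRIC_NAMES:
        raise DomainError(f"unknown metric {metric!r}")
    vals = [
        getattr(r.metrics, metric)
        for r in records
        if r.group == group and (band is None or r.band_name == band)
    ]
    return np.asarray(vals, dtype=float)


def combined_band_metric(records: Sequence[CohortRecord],
                         metric: str) -> pd.DataFrame:
    """Per-sample metric combined over all pathological bands.

    total_count and max_degree combine naturally (sum / max over bands);
    average_count is averaged over bands. One row per (sample_id, group).
    """
    frame = records_to_frame(records)
    agg = {"total_count": "sum", "max_degree": "max", "average_count": "mean"}[
        metric
    ]
    return (
        frame.groupby(["sample_id", "group"], as_index=False)[metric].agg(agg)
    )


def welch_metric_test(
    records: Sequence[CohortRecord],
    metric: str = "total_count",
    band: str | None = None,
    alpha: float = 0.05,
) -> WelchResult:
    """Welch test of DILD vs normal for one metric.

    ``band=None`` combines the pathological bands per sample first
    (sum for total_count, max for max_degree, mean for average_count);
    otherwise only records of the named band are compared.
    """
    if band is None:
        per_sample = combined_band_metric(records, metric)
        x_d = per_sample.loc[per_sample.group == DILD, metric].to_numpy()
        x_n = per_sample.loc[per_sample.group == NORMAL, metric].to_numpy()
    else:
        x_d = _metric_values(records, metric, DILD, band)
        x_n = _metric_values(records, metric, NORMAL, band)
    if x_d.size < 2 or x_n.size < 2:
        raise InsufficientDataError("need >= 2 samples per group")
    return welch_from_samples(x_d, x_n, alpha=alpha)


def sd_separation(
    records: Sequence[CohortRecord],
    metric: str = "total_count",
    band: str | None = None,
) -> tuple[float, float, float, float]:
    """Standard-deviation contrast between the two groups.

    Returns (sd_dild, sd_normal, rel_pct_dild, rel_pct_normal); the relative
    percentages are each group's SD as a share of the two SDs' sum, so they
    always total 100.
    """
    if band is None:
        per_sample = combined_band_metric(records, metric)
        x_d = per_sample.loc[per_sample.group == DILD, metric].to_numpy()
        x_n = per_sample.loc[per_sample.group == NORMAL, metric].to_numpy()
    else:
        x_d = _metric_values(records, metric, DILD, band)
        x_n = _metric_values(records, metric, NORMAL, band)
    if x_d.size < 2 or x_n.size < 2:
        raise InsufficientDataError("need >= 2 records per group")
    sd_d = float(x_d.std(ddof=1))
    sd_n = float(x_n.std(ddof=1))
    total = sd_d + sd_n
    if total == 0:
        raise UndefinedStatisticError("both groups have zero SD")
    return sd_d, sd_n, 100.0 * sd_d / total, 100.0 * sd_n / total


def rd_metric_mm(rd_px: float, pixel_spacing_mm: float) -> float:
    """Physical reach of the connection radius, in millimetres."""
    if rd_px <= 0 or pixel_spacing_mm <= 0:
        raise DomainError("rd and pixel spacing must be positive")
    return rd_px * pixel_spacing_mm
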