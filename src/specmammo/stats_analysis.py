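"""Nonparametric statistics for dose-CNR series.

The dose study asks two questions: does the CNR of each method correlate with
the mean glandular dose (Spearman rank correlation, significance via the
t transform t = r sqrt(n-2)/sqrt(1-r^2)), and do the methods differ overall
(Kruskal-Wallis rank-sum H, compared against a chi-square critical value)?

Poisson counting statistics imply CNR proportional to sqrt(dose), so each
series is summarised by a zero-intercept root fit CNR = a sqrt(MGD); matched-
CNR dose ratios between methods follow as (a2/a1)^2 and express statements
like "the same CNR at 33% less dose".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


def spearman_r(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mean ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("spearman_r needs two equal-length 1-D samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sample")
    return float(sps.spearmanr(x, y).statistic)


def t_from_r(r: float, n: int) -> float:
    """t statistic of a correlation coefficient: t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("t_from_r needs at least 3 observations")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation coefficient must lie in [-1, 1]")
    if abs(r) == 1.0:
        return math.inf if r > 0 else -math.inf
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def critical_value(distribution: str, alpha: float, df: int) -> float:
    """Two-sided Student-t or one-sided chi-square critical value."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("degrees of freedom must be at least 1")
    if distribution == "t":
        return float(sps.t.ppf(1.0 - alpha / 2.0, df))
    if distribution == "chi2":
        return float(sps.chi2.ppf(1.0 - alpha, df))
    raise ValueError("distribution must be 't' or 'chi2'")


def kruskal_wallis(groups, tie_correction: bool = False) -> float:
    """Kruskal-Wallis H from joint mean ranks.

    H = 12 / (n (n+1)) * sum_j T_j^2 / n_j - 3 (n+1), with T_j the rank sum of
    group j.  Ties receive mean ranks; by default the raw (uncorrected) H is
    returned, with the conventional tie-corrected variant behind a flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis needs at least two non-empty groups")
    n = sum(g.size for g in groups)
    if n < 3:
        raise ValueError("kruskal_wallis needs at least 3 observations in total")
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        t_j = ranks[start:start + g.size].sum()
        h += t_j**2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    if tie_correction:
        _, counts = np.unique(pooled, return_counts=True)
        correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
        if correction > 0:
            h /= correction
    return float(h)


@dataclass
class DoseCnrSeries:
    """One method's (MGD, CNR) measurements across the exposure ladder."""

    method_label: str
    mgd_mgy: np.ndarray
    cnr: np.ndarray

    def __post_init__(self) -> None:
        self.mgd_mgy = np.asarray(self.mgd_mgy, dtype=float)
        self.cnr = np.asarray(self.cnr, dtype=float)
        if self.mgd_mgy.shape != self.cnr.shape or self.mgd_mgy.ndim != 1:
            raise ValueError("doses and CNR values must be matching 1-D arrays")
        if np.any(self.mgd_mgy <= 0):
            raise ValueError("doses must be positive")

    @property
    def n(self) -> int:
        return self.mgd_mgy.size


def fit_root(series: DoseCnrSeries) -> float:
    """Least-squares coefficient of the zero-intercept root model CNR = a sqrt(D).

    Closed form a = sum(sqrt(D_i) CNR_i) / sum(D_i); counting statistics force
    proportionality through the origin, so no intercept is fitted by default.
    """
    if series.n < 3:
        raise ValueError("root fit needs at least 3 points")
    d = series.mgd_mgy
    if np.all(d == 0):
        raise ValueError("degenerate series: all doses zero")
    return float(np.sum(np.sqrt(d) * series.cnr) / np.sum(d))


def fit_root_with_intercept(series: DoseCnrSeries) -> tuple[float, float]:
    """Non-default variant CNR = a sqrt(D) + c (least squares)."""
    x = np.sqrt(series.mgd_mgy)
    a, c = np.polyfit(x, series.cnr, 1)
    return float(a), float(c)


def fit_power(series: DoseCnrSeries) -> tuple[float, float]:
    """Free-exponent fit CNR = a D^b by log-log least squares."""
    if np.any(series.cnr <= 0):
        raise ValueError("power-law fit needs positive CNR values")
    b, log_a = np.polyfit(np.log(series.mgd_mgy), np.log(series.cnr), 1)
    return float(np.exp(log_a)), float(b)


def dose_at_cnr(fit_a: float, cnr_target: float) -> float:
    """Dose (mGy) at which the root model reaches ``cnr_target``."""
    if fit_a <= 0:
        raise ValueError("root-fit coefficient must be positive")
    if cnr_target <= 0:
        raise ValueError("target CNR must be positive")
    return (cnr_target / fit_a) ** 2


@dataclass
class SeriesStats:
    """Correlation statistics of one dose-CNR series."""

    method_label: str
    n: int
    r: float
    r_squared: float
    t_calc: float
    t_crit: float
    reject_null: bool
    fit_a: float


@dataclass
class StatsReport:
    """Statistical layer of the dose study: per-series correlations + group test."""

    series_stats: list[SeriesStats] = field(default_factory=list)
    h: float | None = None
    h_df: int | None = None
    chi2_crit: float | None = None
    h_reject_null: bool | None = None
    alpha: float = 0.05

    def to_json(self) -> str:
        return json.dumps({
            "alpha": self.alpha,
            "series": [vars(s) for s in self.series_stats],
            "kruskal_wallis": {
                "H": self.h, "df": self.h_df,
                "chi2_crit": self.chi2_crit, "reject_null": self.h_reject_null,
            },
        })


def analyze_series(series_list: list[DoseCnrSeries], alpha: float = 0.05) -> StatsReport:
    """Spearman/t per series plus Kruskal-Wallis across the methods' CNR groups."""
    report = StatsReport(alpha=alpha)
    for s in series_list:
        r = spearman_r(s.mgd_mgy, s.cnr)
        t_calc = t_from_r(r, s.n)
        t_crit = critical_value("t", alpha, s.n - 2)
        report.series_stats.append(SeriesStats(
            method_label=s.method_label, n=s.n, r=r, r_squared=r * r,
            t_calc=t_calc, t_crit=t_crit, reject_null=abs(t_calc) > t_crit,
            fit_a=fit_root(s) if s.n >= 3 else float("nan"),
        ))
    if len(series_list) >= 2:
        report.h = kruskal_wallis([s.cnr for s in series_list])
        report.h_df = len(series_list) - 1
        report.chi2_crit = critical_value("chi2", alpha, report.h_df)
        report.h_reject_null = report.h > report.chi2_crit
    return report
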