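"""Inter-rater reliability and method-agreement statistics.

Implements the one-way, sum-of-squares intraclass correlation for paired
ratings (two ratings per group), the standard error of measurement SEm, the
standard error of a difference Sdiff, the Jacobson–Truax Reliable Change
Index, Bland–Altman limits of agreement, and a paired comparison that falls
back from the paired t test to the Wilcoxon signed-rank test when the
differences are non-normal.

With k groups of two ratings (N = 2k observations):

    MS_between = SS_between / (k - 1)      SD_b = sqrt(MS_between)
    MS_within  = SS_within  / (N - k)      SD_w = sqrt(MS_within)
    ICC  = (SD_b² - SD_w²) / SD_b²
    SEm  = SD_ref · sqrt(1 - ICC)          (SD_ref defaults to SD_b)
    Sdiff = sqrt(2 · SEm²)
    RCI  = (x₂ - x₁) / Sdiff               |RCI| >= 1.96 flags disagreement
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import MealscopeError, RaterTable

RCI_CRITICAL = 1.96


@dataclass(frozen=True)
class ICCResult:
    ss_b: float
    ss_w: float
    df_b: int
    df_w: int
    sd_b: float
    sd_w: float
    icc: float


@dataclass(frozen=True)
class RCIPair:
    group: str
    x1: float
    x2: float
    rci: float
    significant: bool


@dataclass(frozen=True)
class RCIResult:
    sd_ref: float
    icc: float
    sem: float
    sdiff: float
    pairs: tuple[RCIPair, ...]


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_lo: float
    loa_hi: float
    normality_p: float
    loa_applicable: bool


@dataclass(frozen=True)
class PairedCompareResult:
    test: str  # "t" or "wilcoxon" or "degenerate"
    statistic: float
    p_value: float
    normality_p: float
    mean_diff: float


def _pairs_from_table(table: RaterTable) -> np.ndarray:
    """k × 2 array of paired ratings, one row per group."""
    r1, r2 = table.rater_columns()
    return np.column_stack([r1, r2]).astype(float)


def icc_oneway(table: RaterTable) -> ICCResult:
    """One-way sum-of-squares ICC for a two-rater table.

    Each AOI row forms one group with exactly two ratings.  Between-group SS
    is taken about the grand mean over group means (weighted by the 2
    observations per group); within-group SS about each group's own mean.
    ICC can be negative when within-group variance exceeds between-group
    variance; it is reported as computed, with a warning.
    """
    x = _pairs_from_table(table)
    k = x.shape[0]
    if k < 2:
        raise MealscopeError("ICC needs at least 2 groups")
    grand = x.mean()
    group_means = x.mean(axis=1)
    ss_b = float(2.0 * np.sum((group_means - grand) ** 2))
    ss_w = float(np.sum((x - group_means[:, None]) ** 2))
    df_b = k - 1
    df_w = 2 * k - k  # N - k
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_b <= 0:
        raise MealscopeError("no between-group variance: ICC undefined")
    icc = (ms_b - ms_w) / ms_b
    if icc < 0:
        warnings.warn(
            f"within-group variance exceeds between-group variance: ICC={icc:.4f}",
            stacklevel=2,
        )
    return ICCResult(
        ss_b=ss_b,
        ss_w=ss_w,
        df_b=df_b,
        df_w=df_w,
        sd_b=math.sqrt(ms_b),
        sd_w=math.sqrt(ms_w),
        icc=icc,
    )


def sd_between_sample(table: RaterTable) -> float:
    """Between-group SD of the sample: sqrt(MS_between) of the one-way ANOVA."""
    return icc_oneway(table).sd_b


def pearson_r(table: RaterTable) -> float:
    """Product-moment correlation between the two rater columns."""
    r1, r2 = table.rater_columns()
    if len(r1) < 3:
        raise MealscopeError("Pearson correlation needs >= 3 pairs")
    if np.std(r1) == 0 or np.std(r2) == 0:
        raise MealscopeError("zero variance in a rater column")
    return float(stats.pearsonr(r1, r2).statistic)


def rci_analysis(
    table: RaterTable, sd_ref: float | None = None, icc: float | None = None
) -> RCIResult:
    """Reliable Change Index for every rating pair in the table.

    ``sd_ref`` defaults to the between-group SD of the sample and ``icc`` to
    the one-way ICC of the same table — with those defaults SEm equals the
    within-group SD algebraically.
    """
    if sd_ref is None or icc is None:
        fit = icc_oneway(table)
        sd_ref = fit.sd_b if sd_ref is None else sd_ref
        icc = fit.icc if icc is None else icc
    if icc > 1:
        raise MealscopeError(f"ICC {icc} exceeds 1")
    if sd_ref <= 0:
        raise MealscopeError("reference SD must be positive")
    sem = sd_ref * math.sqrt(max(1.0 - icc, 0.0))
    sdiff = math.sqrt(2.0 * sem**2)
    if sdiff == 0:
        raise MealscopeError("Sdiff is zero: raters agree exactly, RCI undefined")
    pairs = tuple(
        RCIPair(
            group=f"{row.aoi.value}:{row.video_id}",
            x1=row.r1_pct,
            x2=row.r2_pct,
            rci=(row.r2_pct - row.r1_pct) / sdiff,
            significant=abs(row.r2_pct - row.r1_pct) / sdiff >= RCI_CRITICAL,
        )
        for row in table.rows
    )
    return RCIResult(sd_ref=sd_ref, icc=icc, sem=sem, sdiff=sdiff, pairs=pairs)


def bland_altman(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> BlandAltman:
    """Bland–Altman limits of agreement: mean difference ± 1.96 SD.

    A Shapiro–Wilk test on the differences is attached; when the differences
    are non-normal at ``alpha`` the limits are flagged not applicable (they
    are still reported).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise MealscopeError("Bland–Altman needs >= 3 equal-length pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.allclose(d, d[0]):
        p = 1.0  # constant differences: trivially no evidence against normality
    else:
        with warnings.catch_warnings():
            # Shapiro-Wilk p is approximate above n=5000; fine for a gate
            warnings.simplefilter("ignore", UserWarning)
            p = float(stats.shapiro(d).pvalue)
    return BlandAltman(
        mean_diff=mean,
        sd_diff=sd,
        loa_lo=mean - 1.96 * sd,
        loa_hi=mean + 1.96 * sd,
        normality_p=p,
        loa_applicable=p >= alpha,
    )


def paired_compare(
    x: np.ndarray, y: np.ndarray, normality_alpha: float = 0.05
) -> PairedCompareResult:
    """Paired t test, or Wilcoxon signed-rank when differences are non-normal.

    Normality of the paired differences is assessed with Shapiro–Wilk at
    ``normality_alpha``.  All-zero differences are degenerate (no evidence of
    any difference) and reported as such with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise MealscopeError("paired comparison needs >= 3 equal-length pairs")
    d = x - y
    if np.all(d == 0):
        return PairedCompareResult(
            test="degenerate", statistic=0.0, p_value=1.0, normality_p=1.0, mean_diff=0.0
        )
    if np.allclose(d, d[0]):
        norm_p = 1.0
    else:
        norm_p = float(stats.shapiro(d).pvalue)
    if norm_p >= normality_alpha:
        res = stats.ttest_rel(x, y)
        return PairedCompareResult(
            test="t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            normality_p=norm_p,
            mean_diff=float(d.mean()),
        )
    res = stats.wilcoxon(x, y)
    return PairedCompareResult(
        test="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=norm_p,
        mean_diff=float(d.mean()),
    )
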