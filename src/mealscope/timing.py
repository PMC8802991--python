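"""Blood-extraction timing compliance.

Deviation is *target minus actual* time, so a draw taken after its scheduled
time has a negative deviation.  The summary reports the mean, SD and a
t-based 95 % confidence interval of the deviations, lateness-magnitude bins,
the proportions of draws within 1 and 2 minutes of target, and the share of
mealtime occupied by draws that coincide with eating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import ExtractionEvent, MealscopeError
from .microstructure import ExclusionWindow

#: right-closed lateness bins in seconds (by |deviation| for late draws)
LATE_BIN_EDGES = (0.0, 60.0, 120.0, 180.0, 300.0)
LATE_BIN_NAMES = (
    "late_0_60",
    "late_60_120",
    "late_120_180",
    "late_180_300",
    "late_gt_300",
)


@dataclass(frozen=True)
class ComplianceSummary:
    n: int
    mean_dev_s: float
    sd_dev_s: float
    ci95: tuple[float, float]
    bins: dict[str, int]
    prop_within_1min: float
    prop_within_2min: float


def deviation(event: ExtractionEvent) -> float:
    """Target minus actual extraction time; negative means a late draw."""
    return event.target_t - event.actual_t


def _bin_of(dev: float) -> str:
    if dev >= 0:
        return "early_or_on_time"
    late = -dev
    for name, lo, hi in zip(LATE_BIN_NAMES, LATE_BIN_EDGES, LATE_BIN_EDGES[1:]):
        if lo < late <= hi:
            return name
    return LATE_BIN_NAMES[-1]


def summarize_compliance(events: list[ExtractionEvent]) -> ComplianceSummary:
    """Mean/SD/95 % CI of deviations plus lateness bins and within-k-min rates."""
    if not events:
        raise MealscopeError("no extraction events")
    devs = np.array([deviation(e) for e in events], dtype=float)
    n = len(devs)
    mean = float(devs.mean())
    sd = float(devs.std(ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    else:
        half = 0.0
    bins = {"early_or_on_time": 0, **{name: 0 for name in LATE_BIN_NAMES}}
    for d in devs:
        bins[_bin_of(d)] += 1
    return ComplianceSummary(
        n=n,
        mean_dev_s=mean,
        sd_dev_s=sd,
        ci95=(mean - half, mean + half),
        bins=bins,
        prop_within_1min=100.0 * float(np.mean(np.abs(devs) <= 60.0)),
        prop_within_2min=100.0 * float(np.mean(np.abs(devs) <= 120.0)),
    )


def meal_fraction(durations_s: list[float], meal_duration_s: float) -> float:
    """Percentage of mealtime occupied by extractions."""
    if meal_duration_s <= 0:
        raise MealscopeError("meal duration must be positive")
    return 100.0 * float(np.sum(durations_s)) / meal_duration_s


def events_to_exclusion_windows(
    events: list[ExtractionEvent], meal_span: tuple[float, float]
) -> list[ExclusionWindow]:
    """Convert draws that overlap the meal span into exclusion windows.

    Draws entirely outside the recording (e.g., the fasting and post-meal
    samples) are ignored; partially overlapping draws are clipped.
    """
    t0, t1 = meal_span
    windows = []
    for e in events:
        start, end = e.actual_t, e.actual_t + e.duration_s
        if end <= t0 or start >= t1 or e.duration_s == 0:
            continue
        windows.append(
            ExclusionWindow(
                t_start=max(start, t0),
                t_end=min(end, t1),
                reason=f"blood draw {e.label_min} min",
            )
        )
    return windows
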