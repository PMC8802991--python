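"""Meal-microstructure extraction from plate-weight streams.

The concealed balance reports plate weight every ~2 s at 0.1 g resolution.
From that stream this module derives the classic cumulative-intake-curve
variables: number and mean size of bites (consecutive weight decreases),
eating rate in g/min, and the deceleration rate in g/s² defined as |2a| of a
least-squares quadratic fit C(t) = a·t² + b·t + c to cumulative intake.
Blood-draw pauses are handled as exclusion windows whose total length is
subtracted from the meal duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import MealscopeError, WeightSample, WeightSeries

#: default minimum weight drop accepted as a bite, in grams.  The balance
#: resolves 0.1 g but sub-gram dips are indistinguishable from vibration noise.
DEFAULT_MIN_BITE_G = 1.0

#: sessions with more than this many artifact flags are marked invalid
DEFAULT_ARTIFACT_BUDGET = 3


@dataclass(frozen=True)
class ExclusionWindow:
    """Time span removed from the meal (e.g., a blood draw)."""

    t_start: float
    t_end: float
    reason: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise MealscopeError("exclusion window must have t_end > t_start")

    @property
    def length_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class MicrostructureResult:
    """Per-session microstructure summary."""

    session_id: str
    meal_duration_min: float
    n_bites: int
    mean_bite_g: float
    total_consumed_g: float
    eating_rate_g_min: float
    deceleration_g_s2: float
    deceleration_sign: int
    excluded_s: float
    artifact_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "meal_duration_min": self.meal_duration_min,
            "n_bites": self.n_bites,
            "mean_bite_g": self.mean_bite_g,
            "total_consumed_g": self.total_consumed_g,
            "eating_rate_g_min": self.eating_rate_g_min,
            "deceleration_g_s2": self.deceleration_g_s2,
            "deceleration_sign": self.deceleration_sign,
            "excluded_s": self.excluded_s,
            "artifact_flags": list(self.artifact_flags),
        }


def merge_windows(windows: list[ExclusionWindow]) -> list[ExclusionWindow]:
    """Normalize windows: sort and merge overlapping/adjacent spans."""
    if not windows:
        return []
    ordered = sorted(windows, key=lambda w: w.t_start)
    merged = [ordered[0]]
    for w in ordered[1:]:
        last = merged[-1]
        if w.t_start <= last.t_end:
            if w.t_end > last.t_end:
                reason = last.reason if last.reason == w.reason else f"{last.reason}+{w.reason}"
                merged[-1] = ExclusionWindow(last.t_start, w.t_end, reason)
        else:
            merged.append(w)
    return merged


def detect_bites(
    series: WeightSeries, min_bite_g: float = DEFAULT_MIN_BITE_G
) -> tuple[list[tuple[float, float]], list[str]]:
    """Detect bites as consecutive-sample weight decreases >= ``min_bite_g``.

    Returns ``(bites, artifact_flags)`` where each bite is ``(t, grams)`` with
    ``t`` the time of the post-bite sample.  Positive weight jumps (plate
    touched, pressure on the table) are reported as artifact flags, never as
    negative bites.
    """
    if min_bite_g < 0.1:
        raise MealscopeError("min_bite_g below the 0.1 g scale resolution")
    if len(series.samples) < 2:
        raise MealscopeError("need at least 2 samples to detect bites")
    bites: list[tuple[float, float]] = []
    flags: list[str] = []
    for a, b in zip(series.samples, series.samples[1:]):
        delta = a.w - b.w
        if delta >= min_bite_g - 1e-9:
            bites.append((b.t, round(delta, 6)))
        elif delta < -1e-9:
            flags.append(f"weight increase of {-delta:.1f} g at t={b.t:g} s")
    return bites, flags


def mean_bite_size(bites: list[tuple[float, float]]) -> float:
    """Arithmetic mean bite size in grams."""
    if not bites:
        raise MealscopeError("mean bite size undefined: no bites detected")
    return float(np.mean([g for _, g in bites]))


def apply_exclusions(
    series: WeightSeries, windows: list[ExclusionWindow]
) -> tuple[WeightSeries, float]:
    """Drop samples inside exclusion windows; return the trimmed series and
    the total excluded seconds (after merging overlaps).

    Retained samples keep their original timestamps so that curvature of the
    intake curve stays physically interpretable.
    """
    if not windows:
        return series, 0.0
    t0, t1 = series.samples[0].t, series.samples[-1].t
    for w in windows:
        if w.t_start < t0 - 1e-9 or w.t_end > t1 + 1e-9:
            raise MealscopeError(
                f"exclusion window [{w.t_start}, {w.t_end}] outside recording span [{t0}, {t1}]"
            )
    merged = merge_windows(windows)
    excluded_s = sum(w.length_s for w in merged)

    def inside(t: float) -> bool:
        return any(w.t_start <= t <= w.t_end for w in merged)

    kept = [s for s in series.samples if not inside(s.t)]
    if len(kept) < 2:
        raise MealscopeError("exclusions removed almost the entire series")
    trimmed = WeightSeries(
        session_id=series.session_id,
        plate=series.plate,
        samples=kept,
        nominal_dt=series.nominal_dt,
    )
    return trimmed, float(excluded_s)


def eating_rate(total_consumed_g: float, meal_duration_min: float) -> float:
    """Grams consumed per minute."""
    if meal_duration_min <= 0:
        raise MealscopeError("meal duration must be positive")
    return total_consumed_g / meal_duration_min


def deceleration_rate(series: WeightSeries) -> tuple[float, int]:
    """Deceleration of the cumulative-intake curve, in g/s².

    Fits C(t) = a·t² + b·t + c by least squares to cumulative intake
    (initial weight minus weight at t) and returns ``(|2a|, sign(a))``.
    Negative ``a`` means intake decelerates toward the end of the meal.
    """
    t = np.asarray(series.t, dtype=float)
    if len(t) < 3 or len(np.unique(t)) < 3:
        raise MealscopeError("need >= 3 distinct time points for the quadratic fit")
    w = np.asarray(series.w, dtype=float)
    intake = w[0] - w
    a, _b, _c = np.polyfit(t, intake, 2)
    sign = 0 if a == 0 else (1 if a > 0 else -1)
    return float(abs(2.0 * a)), sign


def summarize(
    series: WeightSeries,
    windows: list[ExclusionWindow] | None = None,
    min_bite_g: float = DEFAULT_MIN_BITE_G,
    artifact_budget: int = DEFAULT_ARTIFACT_BUDGET,
) -> MicrostructureResult:
    """Full microstructure summary for one session.

    ``meal_duration_min`` is the raw recording span minus excluded time;
    eating rate is total consumed over that effective duration.  Bites are
    detected on the exclusion-trimmed series.
    """
    windows = windows or []
    trimmed, excluded_s = apply_exclusions(series, windows)
    raw_span = series.span_s
    duration_min = (raw_span - excluded_s) / 60.0
    bites, flags = detect_bites(trimmed, min_bite_g)
    total = round(series.samples[0].w - series.samples[-1].w, 6)
    rate = eating_rate(total, duration_min)
    decel, sign = deceleration_rate(trimmed)
    return MicrostructureResult(
        session_id=series.session_id,
        meal_duration_min=duration_min,
        n_bites=len(bites),
        mean_bite_g=mean_bite_size(bites) if bites else float("nan"),
        total_consumed_g=total,
        eating_rate_g_min=rate,
        deceleration_g_s2=decel,
        deceleration_sign=sign,
        excluded_s=excluded_s,
        artifact_flags=flags,
    )


def session_is_valid(result: MicrostructureResult, artifact_budget: int = DEFAULT_ARTIFACT_BUDGET) -> bool:
    """A session exceeding the artifact budget is marked invalid."""
    return len(result.artifact_flags) <= artifact_budget
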