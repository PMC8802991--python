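"""Seeded generators emulating every input stream of the platform.

Each generator draws from its own pseudo-random stream, derived from the user
seed plus a fixed per-generator offset, so regenerating one stream never
shifts another.  Defaults reflect the magnitudes observed in laboratory
lunches eaten from a 25 cm plate: ~10-minute meals consumed at ~30 g/min in
~3.5 g bites with a mildly decelerating cumulative-intake curve, 50 Hz gaze
recordings, and blood draws that run a few seconds late on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .datamodel import (
    AOILabel,
    AOITimeline,
    ExtractionEvent,
    GazeRecording,
    GazeSample,
    MealscopeError,
    PlateCondition,
    RaterRow,
    RaterTable,
    WeightSample,
    WeightSeries,
    round_to_resolution,
)

# fixed per-generator offsets for stream separation
_OFFSET_WEIGHT = 101
_OFFSET_GAZE = 202
_OFFSET_RATERS = 303
_OFFSET_TIMING = 404


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(offset,)))


@dataclass
class MealSimParams:
    """Parameters of the simulated plate-weight stream.

    Cumulative intake follows C(t) = linear_rate·t + quad_coeff·t² (negative
    ``quad_coeff`` means the meal decelerates), discretized into bites of
    ~N(bite_mean_g, bite_sd_g) sampled on a ``dt_s`` grid with 0.1 g rounding.
    """

    seed: int
    duration_s: float = 630.0
    initial_g: float = 400.0
    linear_rate: float = 0.85  # g/s
    quad_coeff: float = -0.00055  # g/s²; |2a| = 0.0011 g/s² deceleration
    bite_mean_g: float = 3.5
    bite_sd_g: float = 0.8
    pause_prob: float = 0.1
    scale_noise_sd_g: float = 0.0
    dt_s: float = 2.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise MealscopeError("duration must be positive")
        if self.bite_mean_g < 0.1:
            raise MealscopeError("bite mean below the 0.1 g scale resolution")

    def cumulative_intake(self, t: float) -> float:
        return self.linear_rate * t + self.quad_coeff * t * t


@dataclass
class GazeSimParams:
    """Parameters of the simulated gaze stream.

    The fixation schedule drives gaze to AOI polygon centroids with pixel
    jitter; between fixations the gaze sweeps linearly over ``saccade_ms``.
    ``dropout_prob`` invalidates samples at random; ``aoi_drift_px_per_s``
    adds a slow positional drift emulating head movement.
    """

    seed: int
    schedule: list[tuple[AOILabel, float]] = field(default_factory=list)  # (label, ms)
    saccade_ms: float = 40.0
    dropout_prob: float = 0.0
    jitter_px: float = 2.0
    aoi_drift_px_per_s: float = 0.0
    sampling_hz: float = 50.0

    def __post_init__(self) -> None:
        if not self.schedule:
            raise MealscopeError("empty fixation schedule")
        if self.sampling_hz <= 0:
            raise MealscopeError("sampling_hz must be positive")


def gen_weight_stream(params: MealSimParams, session_id: str = "sim-meal",
                      plate: PlateCondition = PlateCondition.CONTROL) -> WeightSeries:
    """Simulate a plate-weight stream; deterministic for a given seed."""
    peak_intake = max(
        params.cumulative_intake(params.duration_s), params.cumulative_intake(0.0)
    )
    if params.quad_coeff < 0:
        t_vertex = -params.linear_rate / (2 * params.quad_coeff)
        if 0 < t_vertex < params.duration_s:
            peak_intake = max(peak_intake, params.cumulative_intake(t_vertex))
    if peak_intake > params.initial_g:
        raise MealscopeError(
            f"intake model consumes {peak_intake:.1f} g but the plate holds {params.initial_g} g"
        )
    rng = _rng(params.seed, _OFFSET_WEIGHT)
    times = np.arange(0.0, params.duration_s + params.dt_s / 2, params.dt_s)
    consumed = 0.0
    next_bite = max(0.1, rng.normal(params.bite_mean_g, params.bite_sd_g))
    samples = []
    for i, t in enumerate(times):
        target = max(0.0, params.cumulative_intake(float(t)))
        if rng.uniform() >= params.pause_prob:
            while consumed + next_bite <= target:
                consumed += next_bite
                next_bite = max(0.1, rng.normal(params.bite_mean_g, params.bite_sd_g))
        if i == len(times) - 1 and target - consumed >= 0.1:
            # the meal ends with a final partial mouthful that completes the
            # planned intake, so total consumption matches the model curve
            consumed = target
        noise = rng.normal(0.0, params.scale_noise_sd_g) if params.scale_noise_sd_g > 0 else 0.0
        w = max(0.0, params.initial_g - consumed + noise)
        samples.append(WeightSample(t=float(t), w=round_to_resolution(w)))
    return WeightSeries(session_id=session_id, plate=plate, samples=samples,
                        nominal_dt=params.dt_s)


def gen_gaze_stream(
    params: GazeSimParams,
    timeline: AOITimeline,
    session_id: str = "sim-gaze",
    plate: PlateCondition = PlateCondition.CONTROL,
    scene_size: tuple[int, int] = (1920, 1080),
) -> GazeRecording:
    """Simulate a gaze stream against an AOI timeline.

    Scheduled fixations must reference AOIs present in the timeline; the
    schedule may not outrun a multi-keyframe timeline's span.
    """
    from .aoi import polygons_at

    n_fix = len(params.schedule)
    total_s = (
        sum(ms for _, ms in params.schedule) + params.saccade_ms * (n_fix - 1)
    ) / 1000.0
    if len(timeline.keyframes) > 1 and total_s > timeline.span_s + 1e-9:
        raise MealscopeError(
            f"schedule ({total_s:.1f} s) outruns the AOI timeline ({timeline.span_s:.1f} s)"
        )
    rng = _rng(params.seed, _OFFSET_GAZE)
    period = 1.0 / params.sampling_hz

    def centroid(label: AOILabel, t: float) -> tuple[float, float]:
        polys = polygons_at(timeline, t)
        if label not in polys:
            raise MealscopeError(f"scheduled AOI {label.value} absent from timeline at t={t:g}")
        c = Polygon(polys[label]).centroid
        return c.x, c.y

    # build piecewise segments: fixation (hold) / saccade (sweep)
    segments = []  # (t0, t1, kind, (x0,y0), (x1,y1))
    t_cursor = 0.0
    prev_xy = None
    for label, dur_ms in params.schedule:
        xy = centroid(label, t_cursor)
        if prev_xy is not None and params.saccade_ms > 0:
            t1 = t_cursor + params.saccade_ms / 1000.0
            segments.append((t_cursor, t1, "saccade", prev_xy, xy))
            t_cursor = t1
        t1 = t_cursor + dur_ms / 1000.0
        segments.append((t_cursor, t1, "fixation", xy, xy))
        t_cursor = t1
        prev_xy = xy

    samples = []
    t = 0.0
    for t0, t1, kind, a, b in segments:
        while t < t1 - 1e-12:
            if kind == "fixation":
                x, y = a
                x += rng.normal(0.0, params.jitter_px)
                y += rng.normal(0.0, params.jitter_px)
            else:
                frac = (t - t0) / (t1 - t0)
                x = a[0] + frac * (b[0] - a[0])
                y = a[1] + frac * (b[1] - a[1])
            x += params.aoi_drift_px_per_s * t
            y += params.aoi_drift_px_per_s * t
            valid = rng.uniform() >= params.dropout_prob
            if valid:
                x = min(max(x, 0.0), float(scene_size[0]))
                y = min(max(y, 0.0), float(scene_size[1]))
                samples.append(GazeSample(t=round(t, 9), x=x, y=y, valid=True))
            else:
                samples.append(
                    GazeSample(t=round(t, 9), x=float("nan"), y=float("nan"), valid=False)
                )
            t += period
    return GazeRecording(
        session_id=session_id,
        plate=plate,
        samples=samples,
        sampling_hz=params.sampling_hz,
        scene_size=scene_size,
    )


def gen_dual_rater_table(
    true_props: dict[str, dict[AOILabel, float]],
    misclass_rate: float,
    seed: int,
) -> RaterTable:
    """Simulate a two-rater % fixation-time table from true dwell proportions.

    ``true_props`` maps video id → {AOI: true percentage} (each video summing
    to 100).  Each rater independently misclassifies a ``misclass_rate``
    fraction of every AOI's mass, redistributing it to the other AOIs of the
    same video; columns are renormalized to 100.  Rate 0 reproduces the truth
    for both raters (ICC = 1).
    """
    if misclass_rate < 0:
        raise MealscopeError("misclassification rate must be >= 0")
    rng = _rng(seed, _OFFSET_RATERS)
    rows: list[RaterRow] = []
    for video_id, props in true_props.items():
        labels = list(props.keys())
        truth = np.array([props[lab] for lab in labels], dtype=float)
        if abs(truth.sum() - 100.0) > 0.5:
            raise MealscopeError(f"video {video_id}: proportions sum to {truth.sum():.2f}, not 100")
        cols = []
        for _rater in range(2):
            col = truth.copy()
            if misclass_rate > 0:
                moved = misclass_rate * truth
                col = col - moved
                for i, m in enumerate(moved):
                    weights = rng.dirichlet(np.ones(len(labels) - 1))
                    others = [j for j in range(len(labels)) if j != i]
                    for j, wgt in zip(others, weights):
                        col[j] += m * wgt
            col = 100.0 * col / col.sum()
            cols.append(col)
        for i, lab in enumerate(labels):
            rows.append(
                RaterRow(aoi=lab, video_id=video_id, r1_pct=float(cols[0][i]), r2_pct=float(cols[1][i]))
            )
    return RaterTable(rows=rows)


def gen_extraction_log(
    target_minutes: list[int],
    mean_dev_s: float = -13.0,
    sd_dev_s: float = 54.4,
    duration_mean_s: float = 80.0,
    seed: int = 0,
    n_sessions: int = 1,
) -> list[ExtractionEvent]:
    """Simulate blood-draw logs: normal timing deviations, log-normal durations.

    Deviation is target − actual, so the default mean of −13 s means draws run
    13 s late on average.  One event per target minute per session.
    """
    if sd_dev_s < 0:
        raise MealscopeError("deviation SD must be >= 0")
    rng = _rng(seed, _OFFSET_TIMING)
    sigma = 0.4
    mu = np.log(duration_mean_s) - sigma**2 / 2 if duration_mean_s > 0 else None
    events = []
    for _ in range(n_sessions):
        for m in target_minutes:
            target_t = 60.0 * m
            dev = rng.normal(mean_dev_s, sd_dev_s) if sd_dev_s > 0 else mean_dev_s
            dur = float(rng.lognormal(mu, sigma)) if mu is not None else 0.0
            events.append(
                ExtractionEvent(
                    label_min=int(m),
                    target_t=target_t,
                    actual_t=max(0.0, target_t - dev),
                    duration_s=dur,
                )
            )
    return events


def square_plate_timeline(
    n_keyframes: int = 1,
    interval_s: float = 10.0,
    scene_size: tuple[int, int] = (1920, 1080),
    shrink_per_keyframe: float = 0.0,
) -> AOITimeline:
    """Convenience timeline: four rectangular AOIs laid out on the scene.

    Rice top-left, vegetables top-right, meatballs bottom-left, plate border
    as a thin frame strip at the bottom-right.  ``shrink_per_keyframe``
    shrinks the food AOIs at each keyframe to emulate food disappearing.
    """
    from .datamodel import AOIKeyframe

    w, h = scene_size
    keyframes = []
    for i in range(n_keyframes):
        s = 1.0 - shrink_per_keyframe * i
        if s <= 0.05:
            raise MealscopeError("AOIs shrank away; lower shrink_per_keyframe")

        def rect(x0, y0, x1, y1, scale=s):
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            hw, hh = (x1 - x0) / 2 * scale, (y1 - y0) / 2 * scale
            return [(cx - hw, cy - hh), (cx + hw, cy - hh), (cx + hw, cy + hh), (cx - hw, cy + hh)]

        keyframes.append(
            AOIKeyframe(
                t=i * interval_s,
                polygons={
                    AOILabel.RICE: rect(0.1 * w, 0.1 * h, 0.45 * w, 0.45 * h),
                    AOILabel.VEGETABLES: rect(0.55 * w, 0.1 * h, 0.9 * w, 0.45 * h),
                    AOILabel.MEATBALLS: rect(0.1 * w, 0.55 * h, 0.45 * w, 0.9 * h),
                    AOILabel.BORDER: rect(0.55 * w, 0.55 * h, 0.9 * w, 0.9 * h),
                },
            )
        )
    return AOITimeline(keyframes=keyframes)
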