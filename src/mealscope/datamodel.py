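"""Core domain types shared by every analysis stage.

All times are expressed in seconds from the start of the recording and all
weights in grams; scene-camera coordinates are pixels with the origin at the
top-left corner and y increasing downward (video convention).  Types validate
their invariants on construction so downstream code can assume well-formed
inputs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence


class MealscopeError(ValueError):
    """Base class for domain validation errors."""


class PlateCondition(str, enum.Enum):
    """Plate used in the cross-over design: portion-calibrated or plain control."""

    CALIBRATED = "calibrated"
    CONTROL = "control"


class AOILabel(str, enum.Enum):
    """Areas of interest on the meal plate.

    ``NONE`` marks gaze that falls outside every polygon.  The manual coding
    vocabulary covers all seven food/plate zones; automatic-gaze-mapping
    compatible coding restricts itself to rice, vegetables, meatballs and the
    plate border.
    """

    RICE = "rice"
    VEGETABLES = "vegetables"
    MEATBALLS = "meatballs"
    BORDER = "border"
    EMPTY = "empty"
    MIXED = "mixed"
    BREAD = "bread"
    NONE = "none"


#: deterministic tie-break order used by AGM-compatible assignment
AGM_LABEL_ORDER = (
    AOILabel.RICE,
    AOILabel.VEGETABLES,
    AOILabel.MEATBALLS,
    AOILabel.BORDER,
)

#: AOI labels retained by the AGM-compatible protocol
AGM_LABELS = frozenset(AGM_LABEL_ORDER)


@dataclass(frozen=True)
class WeightSample:
    """One plate-scale reading: time ``t`` (s) and weight ``w`` (g, 0.1 g)."""

    t: float
    w: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise MealscopeError(f"negative timestamp {self.t}")
        if self.w < 0:
            raise MealscopeError(f"negative weight {self.w}")


@dataclass
class WeightSeries:
    """Time-stamped plate-weight stream from the concealed balance.

    The balance reports to 0.1 g nominally every ``nominal_dt`` seconds; the
    series is the raw material from which meal microstructure (bite size,
    eating rate, deceleration) is derived.
    """

    session_id: str
    plate: PlateCondition
    samples: list[WeightSample]
    nominal_dt: float = 2.0

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise MealscopeError("weight series needs at least 2 samples")
        for a, b in zip(self.samples, self.samples[1:]):
            if b.t <= a.t:
                raise MealscopeError(
                    f"timestamps must strictly increase (t={a.t} then t={b.t})"
                )

    @property
    def t(self) -> list[float]:
        return [s.t for s in self.samples]

    @property
    def w(self) -> list[float]:
        return [s.w for s in self.samples]

    @property
    def span_s(self) -> float:
        return self.samples[-1].t - self.samples[0].t


@dataclass(frozen=True)
class GazeSample:
    """One eye-tracker sample; invalid samples carry no usable coordinates."""

    t: float
    x: float
    y: float
    valid: bool

    def __post_init__(self) -> None:
        if self.t < 0:
            raise MealscopeError(f"negative timestamp {self.t}")


@dataclass
class GazeRecording:
    """Gaze-sample stream mapped to scene-camera pixel coordinates."""

    session_id: str
    plate: PlateCondition
    samples: list[GazeSample]
    sampling_hz: float = 50.0
    scene_size: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise MealscopeError("sampling_hz must be positive")
        for a, b in zip(self.samples, self.samples[1:]):
            if b.t < a.t:
                raise MealscopeError(
                    f"timestamps must be non-decreasing (t={a.t} then t={b.t})"
                )

    def valid_samples(self) -> list[GazeSample]:
        return [s for s in self.samples if s.valid]


def _polygon_is_simple(vertices: Sequence[tuple[float, float]]) -> bool:
    # shapely import kept local so the datamodel stays importable cheaply
    from shapely.geometry import Polygon

    if len(vertices) < 3:
        return False
    return Polygon(vertices).is_valid


@dataclass
class AOIKeyframe:
    """AOI polygon set valid from time ``t`` until the next keyframe."""

    t: float
    polygons: dict[AOILabel, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        if self.t < 0:
            raise MealscopeError("keyframe time must be >= 0")
        for label, verts in self.polygons.items():
            if len(verts) < 3:
                raise MealscopeError(f"{label.value}: polygon needs >= 3 vertices")
            if not _polygon_is_simple(verts):
                raise MealscopeError(f"{label.value}: polygon self-intersects")


@dataclass
class AOITimeline:
    """Keyframed AOI polygons; lookup is a left-closed step function.

    The first keyframe must sit at t = 0 so every gaze time has a defined
    polygon set.  Keyframes mirror the manual workflow of re-drawing AOIs at
    regular intervals as food disappears from the plate.
    """

    keyframes: list[AOIKeyframe]

    def __post_init__(self) -> None:
        if not self.keyframes:
            raise MealscopeError("timeline needs at least one keyframe")
        self.keyframes.sort(key=lambda k: k.t)
        if self.keyframes[0].t != 0:
            raise MealscopeError("first keyframe must be at t=0")
        for a, b in zip(self.keyframes, self.keyframes[1:]):
            if b.t <= a.t:
                raise MealscopeError("keyframe times must strictly increase")

    @property
    def span_s(self) -> float:
        return self.keyframes[-1].t


@dataclass(frozen=True)
class Fixation:
    """A quasi-stationary gaze episode with its centroid in scene pixels."""

    t_start: float
    t_end: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise MealscopeError("fixation must have positive duration")

    @property
    def duration_ms(self) -> float:
        return (self.t_end - self.t_start) * 1000.0


EXTRACTION_LABELS_MIN = (0, 5, 10, 30, 60, 90)


@dataclass(frozen=True)
class ExtractionEvent:
    """A blood draw: scheduled minute label, target/actual times, duration."""

    label_min: int
    target_t: float
    actual_t: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.label_min not in EXTRACTION_LABELS_MIN:
            raise MealscopeError(
                f"extraction label {self.label_min} not in {EXTRACTION_LABELS_MIN}"
            )
        if self.duration_s < 0:
            raise MealscopeError("extraction duration must be >= 0")


@dataclass(frozen=True)
class RaterRow:
    aoi: AOILabel
    video_id: str
    r1_pct: float
    r2_pct: float


@dataclass
class RaterTable:
    """Paired % fixation times per AOI from two independent raters.

    Each row is one AOI within one video; ``k`` rows make ``N = 2k`` ratings.
    Within one video each rater's percentages must sum to 100 up to 1-decimal
    rounding slack (±0.5).
    """

    rows: list[RaterRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MealscopeError("rater table is empty")
        for row in self.rows:
            for pct in (row.r1_pct, row.r2_pct):
                if not (0 <= pct <= 100):
                    raise MealscopeError(f"percentage {pct} outside [0, 100]")
        videos = {row.video_id for row in self.rows}
        for vid in videos:
            sub = [r for r in self.rows if r.video_id == vid]
            for col in ("r1_pct", "r2_pct"):
                total = sum(getattr(r, col) for r in sub)
                if not (99.5 - 1e-9 <= total <= 100.5 + 1e-9):
                    raise MealscopeError(
                        f"video {vid} {col} sums to {total:.2f}, outside [99.5, 100.5]"
                    )

    @property
    def k(self) -> int:
        """Number of AOI pairs (ANOVA groups)."""
        return len(self.rows)

    @property
    def n_ratings(self) -> int:
        """Total number of ratings, N = 2k."""
        return 2 * self.k

    def rater_columns(self) -> tuple[list[float], list[float]]:
        return [r.r1_pct for r in self.rows], [r.r2_pct for r in self.rows]


def round_to_resolution(value: float, resolution: float = 0.1) -> float:
    """Quantize a reading to the instrument resolution (default 0.1 g)."""
    return round(round(value / resolution) * resolution, 6)


def seconds_to_minutes(s: float) -> float:
    return s / 60.0


def is_finite(x: float) -> bool:
    return math.isfinite(x)
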