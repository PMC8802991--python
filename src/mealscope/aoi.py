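"""Dynamic area-of-interest assignment and dwell-time summaries.

Fixations are mapped to AOIs by intersecting a circular gaze marker with the
AOI polygons valid at the fixation onset.  Two coding modes are supported:

``manual``
    emulates frame-by-frame human coding: the label with the largest share of
    the covered marker area wins, unless no single AOI dominates (default
    > 60 % of the covered area), in which case the fixation is coded
    ``mixed``.  All seven plate zones are allowed.

``agm_compatible``
    emulates automatic gaze mapping: only rice, vegetables, meatballs and the
    plate border are eligible, the maximum-overlap label always wins (never
    ``mixed``), and ties break deterministically in the order rice <
    vegetables < meatballs < border.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from shapely.geometry import Point, Polygon

from .datamodel import (
    AGM_LABEL_ORDER,
    AGM_LABELS,
    AOILabel,
    AOITimeline,
    Fixation,
    MealscopeError,
)

DEFAULT_MARKER_RADIUS_PX = 20.0
DEFAULT_MIXED_DOMINANCE = 0.60


class CodingMode(str, enum.Enum):
    MANUAL = "manual"
    AGM_COMPATIBLE = "agm_compatible"


@dataclass(frozen=True)
class ForkInterval:
    """Span during which gaze rests on the fork, with the food AOI behind it."""

    t_start: float
    t_end: float
    backing: AOILabel | None

    def covers(self, t: float) -> bool:
        return self.t_start <= t <= self.t_end


@dataclass
class DwellSummary:
    dwell_s: dict[AOILabel, float]
    total_aoi_s: float
    proportional_pct: dict[AOILabel, float]
    window: tuple[float, float]


def polygons_at(timeline: AOITimeline, t: float) -> dict[AOILabel, list[tuple[float, float]]]:
    """Step-function lookup: the latest keyframe with keyframe.t <= t."""
    if t < timeline.keyframes[0].t:
        raise MealscopeError(f"t={t} precedes the first keyframe")
    current = timeline.keyframes[0]
    for kf in timeline.keyframes:
        if kf.t <= t:
            current = kf
        else:
            break
    return current.polygons


def assign_fixation(
    fix: Fixation,
    polygons: dict[AOILabel, list[tuple[float, float]]],
    mode: CodingMode = CodingMode.MANUAL,
    marker_radius_px: float = DEFAULT_MARKER_RADIUS_PX,
    mixed_dominance: float = DEFAULT_MIXED_DOMINANCE,
) -> AOILabel:
    """Assign one fixation to an AOI by circular-marker area overlap.

    The overlap of the gaze marker (disc centred on the fixation centroid)
    with each polygon is computed; proportions are taken over the *covered*
    area (the part of the marker inside any AOI).  ``NONE`` when the marker
    touches no polygon.
    """
    if not polygons:
        raise MealscopeError("empty polygon map")
    if marker_radius_px <= 0:
        raise MealscopeError("marker radius must be positive")
    if mode is CodingMode.AGM_COMPATIBLE:
        polygons = {k: v for k, v in polygons.items() if k in AGM_LABELS}
        if not polygons:
            return AOILabel.NONE

    marker = Point(fix.x, fix.y).buffer(marker_radius_px, quad_segs=64)
    overlaps: dict[AOILabel, float] = {}
    for label, verts in polygons.items():
        area = marker.intersection(Polygon(verts)).area
        if area > 0:
            overlaps[label] = area
    if not overlaps:
        return AOILabel.NONE
    covered = sum(overlaps.values())

    if mode is CodingMode.AGM_COMPATIBLE:
        # deterministic tie-break in the fixed label order
        best, best_area = None, -1.0
        for label in AGM_LABEL_ORDER:
            area = overlaps.get(label, 0.0)
            if area > best_area + 1e-12:
                best, best_area = label, area
        return best if best is not None else AOILabel.NONE

    top_label = max(overlaps, key=lambda lab: overlaps[lab])
    if overlaps[top_label] / covered > mixed_dominance:
        return top_label
    return AOILabel.MIXED


def label_fixations(
    fixations: list[Fixation],
    timeline: AOITimeline,
    mode: CodingMode = CodingMode.MANUAL,
    marker_radius_px: float = DEFAULT_MARKER_RADIUS_PX,
    mixed_dominance: float = DEFAULT_MIXED_DOMINANCE,
) -> list[tuple[Fixation, AOILabel]]:
    """Label every fixation using the polygons valid at its start time."""
    out = []
    for fix in fixations:
        polys = polygons_at(timeline, fix.t_start)
        out.append(
            (fix, assign_fixation(fix, polys, mode, marker_radius_px, mixed_dominance))
        )
    return out


def recode_for_agm(
    labeled: list[tuple[Fixation, AOILabel]],
    fork_intervals: list[ForkInterval] | None = None,
    mixed_recode: AOILabel | None = None,
) -> list[tuple[Fixation, AOILabel]]:
    """Recode manually-coded fixations for comparability with AGM output.

    Fixations whose onset falls in a fork interval take the food AOI declared
    behind the fork; ``mixed`` fixations are replaced by the declared
    most-likely single AOI.  With no fork intervals and no mixed fixations the
    transform is the identity.
    """
    fork_intervals = fork_intervals or []
    for iv in fork_intervals:
        if iv.backing is None:
            raise MealscopeError(
                f"fork interval [{iv.t_start}, {iv.t_end}] lacks a backing AOI"
            )
    out = []
    for fix, label in labeled:
        new_label = label
        for iv in fork_intervals:
            if iv.covers(fix.t_start):
                new_label = iv.backing
                break
        else:
            if label is AOILabel.MIXED:
                if mixed_recode is None:
                    raise MealscopeError(
                        "mixed fixation present but no most-likely AOI declared"
                    )
                new_label = mixed_recode
        out.append((fix, new_label))
    return out


def dwell_summary(
    labeled: list[tuple[Fixation, AOILabel]],
    window: tuple[float, float],
    include_labels: list[AOILabel] | None = None,
) -> DwellSummary:
    """Absolute and proportional dwell per AOI inside a time window.

    Fixations are clipped to the window.  Proportional dwell divides each
    AOI's fixation time by the total fixation time over ``include_labels``
    (default: every label seen except ``NONE``).
    """
    t0, t1 = window
    if t1 <= t0:
        raise MealscopeError("empty dwell window")
    if include_labels is None:
        include_labels = sorted(
            {lab for _, lab in labeled if lab is not AOILabel.NONE},
            key=lambda lab: lab.value,
        )
    dwell = {lab: 0.0 for lab in include_labels}
    for fix, label in labeled:
        if label not in dwell:
            continue
        clipped = min(fix.t_end, t1) - max(fix.t_start, t0)
        if clipped > 0:
            dwell[label] += clipped
    total = sum(dwell.values())
    pct = {
        lab: (100.0 * s / total if total > 0 else 0.0) for lab, s in dwell.items()
    }
    return DwellSummary(dwell_s=dwell, total_aoi_s=total, proportional_pct=pct, window=window)
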