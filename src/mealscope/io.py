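"""Readers and writers for the platform's delimited-text and JSON formats.

Formats
-------
Weight stream      TSV/CSV with columns ``t_s, weight_g``
Gaze stream        TSV/CSV with columns ``t_s, x_px, y_px, valid``
AOI timeline       JSON ``{"keyframes": [{"t": 0, "polygons": {label: [[x, y], ...]}}]}``
Rater table        CSV with columns ``aoi, video_id, r1_pct, r2_pct``
Extraction log     CSV with columns ``label_min, target_s, actual_s, duration_s``

The delimiter (tab or comma) is auto-detected from the header line; the
decimal separator is always a point.
"""

from __future__ import annotations

import json
import logging
import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

from .datamodel import (
    AOIKeyframe,
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

logger = logging.getLogger(__name__)


class FormatError(MealscopeError):
    """Malformed input file."""


def _read_delimited(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    return df


def read_weight_stream(
    path: str | Path,
    session_id: str = "",
    plate: PlateCondition = PlateCondition.CONTROL,
    nominal_dt: float = 2.0,
) -> WeightSeries:
    """Read a plate-weight stream; weights are quantized to 0.1 g on ingest."""
    df = _read_delimited(path, ["t_s", "weight_g"])
    t = df["t_s"].to_numpy(dtype=float)
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            raise FormatError(
                f"non-monotone timestamp at row {i}: t={t[i]} follows t={t[i - 1]}"
            )
    samples = [
        WeightSample(t=float(row.t_s), w=round_to_resolution(float(row.weight_g)))
        for row in df.itertuples()
    ]
    return WeightSeries(
        session_id=session_id or Path(path).stem,
        plate=plate,
        samples=samples,
        nominal_dt=nominal_dt,
    )


def write_weight_stream(series: WeightSeries, path: str | Path) -> None:
    pd.DataFrame({"t_s": series.t, "weight_g": series.w}).to_csv(path, sep="\t", index=False)


def read_gaze_stream(
    path: str | Path,
    scene_size: tuple[int, int] = (1920, 1080),
    session_id: str = "",
    plate: PlateCondition = PlateCondition.CONTROL,
    sampling_hz: float | None = None,
) -> GazeRecording:
    """Read a gaze stream.

    Invalid rows are retained (they are needed for the gaze-capture
    percentage) and may carry empty coordinates.  Valid samples outside the
    scene bounds are clamped with a warning.  When ``sampling_hz`` is not
    given it is inferred from the median inter-sample interval.
    """
    df = _read_delimited(path, ["t_s", "x_px", "y_px", "valid"])
    w, h = scene_size
    samples: list[GazeSample] = []
    prev_t = None
    for i, row in enumerate(df.itertuples()):
        t = float(row.t_s)
        if prev_t is not None and t < prev_t:
            raise FormatError(f"decreasing timestamp at row {i}: {t} < {prev_t}")
        prev_t = t
        valid = bool(int(row.valid))
        if valid:
            x, y = float(row.x_px), float(row.y_px)
            if not (0 <= x <= w) or not (0 <= y <= h):
                warnings.warn(
                    f"row {i}: valid sample ({x}, {y}) outside scene {scene_size}; clamped",
                    stacklevel=2,
                )
                logger.warning("clamped out-of-scene gaze sample at row %d", i)
                x = min(max(x, 0.0), float(w))
                y = min(max(y, 0.0), float(h))
        else:
            x = y = float("nan")
        samples.append(GazeSample(t=t, x=x, y=y, valid=valid))
    if sampling_hz is None:
        ts = sorted(s.t for s in samples)
        dts = [b - a for a, b in zip(ts, ts[1:]) if b > a]
        if dts:
            dts.sort()
            sampling_hz = round(1.0 / dts[len(dts) // 2], 3)
        else:
            sampling_hz = 50.0
    return GazeRecording(
        session_id=session_id or Path(path).stem,
        plate=plate,
        samples=samples,
        sampling_hz=sampling_hz,
        scene_size=scene_size,
    )


def write_gaze_stream(rec: GazeRecording, path: str | Path) -> None:
    rows = [
        {
            "t_s": s.t,
            "x_px": s.x if s.valid else "",
            "y_px": s.y if s.valid else "",
            "valid": int(s.valid),
        }
        for s in rec.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_aoi_timeline(path: str | Path) -> AOITimeline:
    """Read a JSON AOI timeline; keyframes are sorted and polygons validated."""
    with open(path) as fh:
        payload = json.load(fh)
    if "keyframes" not in payload:
        raise FormatError("AOI timeline JSON must contain a 'keyframes' list")
    keyframes = []
    for kf in payload["keyframes"]:
        polygons = {
            AOILabel(label): [tuple(map(float, v)) for v in verts]
            for label, verts in kf["polygons"].items()
        }
        keyframes.append(AOIKeyframe(t=float(kf["t"]), polygons=polygons))
    return AOITimeline(keyframes=keyframes)


def write_aoi_timeline(timeline: AOITimeline, path: str | Path) -> None:
    payload = {
        "keyframes": [
            {
                "t": kf.t,
                "polygons": {
                    label.value: [list(v) for v in verts]
                    for label, verts in kf.polygons.items()
                },
            }
            for kf in timeline.keyframes
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_rater_table(path: str | Path) -> RaterTable:
    df = _read_delimited(path, ["aoi", "video_id", "r1_pct", "r2_pct"])
    rows = [
        RaterRow(
            aoi=AOILabel(str(row.aoi).strip()),
            video_id=str(row.video_id).strip(),
            r1_pct=float(row.r1_pct),
            r2_pct=float(row.r2_pct),
        )
        for row in df.itertuples()
    ]
    return RaterTable(rows=rows)


def write_rater_table(table: RaterTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "aoi": [r.aoi.value for r in table.rows],
            "video_id": [r.video_id for r in table.rows],
            "r1_pct": [r.r1_pct for r in table.rows],
            "r2_pct": [r.r2_pct for r in table.rows],
        }
    ).to_csv(path, index=False)


def read_extraction_log(path: str | Path) -> list[ExtractionEvent]:
    df = _read_delimited(path, ["label_min", "target_s", "actual_s", "duration_s"])
    return [
        ExtractionEvent(
            label_min=int(row.label_min),
            target_t=float(row.target_s),
            actual_t=float(row.actual_s),
            duration_s=float(row.duration_s),
        )
        for row in df.itertuples()
    ]


def write_extraction_log(events: list[ExtractionEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "label_min": [e.label_min for e in events],
            "target_s": [e.target_t for e in events],
            "actual_s": [e.actual_t for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    ).to_csv(path, index=False)


def load_rater_reliability_fixture() -> RaterTable:
    """Packaged two-rater % fixation-time table (14 AOI pairs, two videos).

    Video A was recorded with the calibrated plate, video B with the control
    plate; values are percentages printed to one decimal.
    """
    ref = resources.files("mealscope.fixtures").joinpath("rater_fixation_table.csv")
    with resources.as_file(ref) as p:
        return read_rater_table(p)
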