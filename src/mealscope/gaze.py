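"""Gaze-recording quality control and velocity-threshold fixation filtering.

Quality control is the *gaze capture* percentage — the share of samples with
valid coordinates — gated at a configurable threshold (default 80 %).
Fixations are classified with an I-VT-style filter: point-to-point angular
velocity is computed over valid samples (central differences inside runs,
one-sided at boundaries), runs below the velocity threshold become candidate
fixations, and candidates shorter than the minimum-duration cut-off
(default 100 ms) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Fixation, GazeRecording, MealscopeError

DEFAULT_CAPTURE_THRESHOLD_PCT = 80.0


@dataclass(frozen=True)
class QCReport:
    n_samples: int
    n_valid: int
    capture_pct: float
    threshold_pct: float
    passes: bool


@dataclass(frozen=True)
class IVTConfig:
    """Settings of the velocity-threshold fixation filter.

    ``velocity_threshold`` is in degrees of visual angle per second (30 °/s is
    the conventional default of commercial I-VT filters); ``deg_per_px``
    converts scene-pixel distances to degrees under a small-angle
    approximation over the plate region.  ``gap_fill_ms`` is the longest
    invalid-sample gap bridged inside a fixation (0 = any dropout breaks it).
    """

    velocity_threshold: float = 30.0
    min_fixation_ms: float = 100.0
    deg_per_px: float = 0.05
    gap_fill_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.min_fixation_ms <= 0 or self.deg_per_px <= 0:
            raise MealscopeError("IVT parameters must be strictly positive")
        if self.gap_fill_ms < 0:
            raise MealscopeError("gap_fill_ms must be >= 0")


def gaze_capture(
    recording: GazeRecording, threshold_pct: float = DEFAULT_CAPTURE_THRESHOLD_PCT
) -> QCReport:
    """Percentage of valid gaze samples, gated at ``threshold_pct``."""
    n = len(recording.samples)
    if n == 0:
        raise MealscopeError("empty gaze recording")
    n_valid = sum(1 for s in recording.samples if s.valid)
    pct = 100.0 * n_valid / n
    return QCReport(
        n_samples=n,
        n_valid=n_valid,
        capture_pct=pct,
        threshold_pct=threshold_pct,
        passes=pct >= threshold_pct,
    )


def _angular_velocities(t: np.ndarray, x: np.ndarray, y: np.ndarray, deg_per_px: float) -> np.ndarray:
    """Point-to-point angular velocity per sample.

    Each sample carries the velocity of the segment from it to the next valid
    sample (the last sample uses its backward segment), the classic
    point-to-point convention of velocity-threshold filters.  Assigning the
    forward segment keeps a stationary sample that immediately precedes or
    follows a saccade inside its fixation.
    """
    n = len(t)
    v = np.zeros(n)
    if n < 2:
        return v
    for i in range(n):
        j, k = (i, i + 1) if i + 1 < n else (i - 1, i)
        dt = t[k] - t[j]
        if dt <= 0:
            v[i] = 0.0
            continue
        dist_px = float(np.hypot(x[k] - x[j], y[k] - y[j]))
        v[i] = deg_per_px * dist_px / dt
    return v


def classify_fixations(recording: GazeRecording, config: IVTConfig) -> list[Fixation]:
    """I-VT fixation classification on the valid samples of a recording.

    Returns time-ordered, disjoint fixations.  A fixation's end time extends
    one sample period past its last member sample so that a steady 500 ms of
    samples yields a 500 ms fixation.  Fewer than two valid samples yield an
    empty list.
    """
    valid = recording.valid_samples()
    if len(valid) < 2:
        return []
    t = np.array([s.t for s in valid])
    x = np.array([s.x for s in valid])
    y = np.array([s.y for s in valid])
    period = 1.0 / recording.sampling_hz
    # nominal spacing plus half a period of jitter, extended by gap filling
    max_gap = 1.5 * period + config.gap_fill_ms / 1000.0

    v = _angular_velocities(t, x, y, config.deg_per_px)
    slow = v < config.velocity_threshold

    fixations: list[Fixation] = []
    run_start = None
    for i in range(len(valid) + 1):
        broken = (
            i == len(valid)
            or not slow[i]
            or (run_start is not None and i > 0 and t[i] - t[i - 1] > max_gap)
        )
        if run_start is not None and broken:
            end = i - 1 if (i == len(valid) or not slow[i]) else i - 1
            _emit_run(fixations, t, x, y, run_start, end, period, config)
            run_start = None
        if i < len(valid) and slow[i] and run_start is None:
            run_start = i
    return fixations


def _emit_run(
    fixations: list[Fixation],
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    start: int,
    end: int,
    period: float,
    config: IVTConfig,
) -> None:
    t_start = float(t[start])
    t_end = float(t[end]) + period
    if (t_end - t_start) * 1000.0 + 1e-9 < config.min_fixation_ms:
        return
    fixations.append(
        Fixation(
            t_start=t_start,
            t_end=t_end,
            x=float(np.mean(x[start : end + 1])),
            y=float(np.mean(y[start : end + 1])),
        )
    )
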