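"""End-to-end session orchestration.

``run_session`` executes the full stage order for one recording session —
gaze QC → blood-draw exclusions → weight microstructure → fixation
classification → AOI dwell → timing compliance — and returns a single
``SessionReport`` whose JSON form echoes every default applied, so a report
is a pure function of its inputs and configuration.  Validity gates (80 %
gaze capture, the weight-artifact budget) only set flags; they never alter
computed numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import io as msio
from .aoi import (
    DEFAULT_MARKER_RADIUS_PX,
    DEFAULT_MIXED_DOMINANCE,
    CodingMode,
    dwell_summary,
    label_fixations,
)
from .datamodel import AOILabel, MealscopeError, PlateCondition
from .gaze import DEFAULT_CAPTURE_THRESHOLD_PCT, IVTConfig, classify_fixations, gaze_capture
from .microstructure import (
    DEFAULT_ARTIFACT_BUDGET,
    DEFAULT_MIN_BITE_G,
    session_is_valid,
    summarize,
)
from .timing import events_to_exclusion_windows, meal_fraction, summarize_compliance

logger = logging.getLogger(__name__)

EARLY_WINDOW_S = 60.0  # onset window emphasised in dwell analysis


class StageError(MealscopeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SessionReport:
    session_id: str
    plate: str
    config_echo: dict
    qc: dict | None = None
    microstructure: dict | None = None
    dwell_first_minute: dict | None = None
    dwell_full: dict | None = None
    compliance: dict | None = None
    validity: dict | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _dwell_to_dict(summary) -> dict:
    return {
        "window": list(summary.window),
        "total_aoi_s": summary.total_aoi_s,
        "dwell_s": {lab.value: v for lab, v in summary.dwell_s.items()},
        "proportional_pct": {lab.value: v for lab, v in summary.proportional_pct.items()},
    }


def load_session_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_session(config: dict[str, Any]) -> SessionReport:
    """Run all stages named in ``config`` for one session.

    Required keys: ``session_id``; optional blocks: ``weights`` (path),
    ``gaze`` (path), ``aoi_timeline`` (path), ``extractions`` (path), plus
    option overrides (``plate``, ``min_bite_g``, ``capture_threshold_pct``,
    ``ivt``, ``marker_radius_px``, ``coding_mode`` ...).  Any stage error
    aborts with the stage name and cause.
    """
    session_id = config.get("session_id", "session")
    plate = PlateCondition(config.get("plate", "control"))
    min_bite_g = float(config.get("min_bite_g", DEFAULT_MIN_BITE_G))
    artifact_budget = int(config.get("artifact_budget", DEFAULT_ARTIFACT_BUDGET))
    capture_threshold = float(
        config.get("capture_threshold_pct", DEFAULT_CAPTURE_THRESHOLD_PCT)
    )
    ivt_kwargs = dict(config.get("ivt", {}))
    ivt = IVTConfig(**ivt_kwargs)
    marker_radius = float(config.get("marker_radius_px", DEFAULT_MARKER_RADIUS_PX))
    mixed_dominance = float(config.get("mixed_dominance", DEFAULT_MIXED_DOMINANCE))
    mode = CodingMode(config.get("coding_mode", "agm_compatible"))

    echo = {
        "min_bite_g": min_bite_g,
        "artifact_budget": artifact_budget,
        "capture_threshold_pct": capture_threshold,
        "ivt": dataclasses.asdict(ivt),
        "marker_radius_px": marker_radius,
        "mixed_dominance": mixed_dominance,
        "coding_mode": mode.value,
        "early_window_s": EARLY_WINDOW_S,
    }
    report = SessionReport(session_id=session_id, plate=plate.value, config_echo=echo)

    events = []
    if config.get("extractions"):
        try:
            events = msio.read_extraction_log(config["extractions"])
        except Exception as exc:
            raise StageError("extractions", exc) from exc

    gaze_rec = None
    if config.get("gaze"):
        try:
            gaze_rec = msio.read_gaze_stream(
                config["gaze"],
                scene_size=tuple(config.get("scene_size", (1920, 1080))),
                session_id=session_id,
                plate=plate,
            )
            qc = gaze_capture(gaze_rec, capture_threshold)
            report.qc = dataclasses.asdict(qc)
            logger.info("QC: capture %.1f%% (threshold %.0f%%)", qc.capture_pct, capture_threshold)
        except Exception as exc:
            raise StageError("gaze_qc", exc) from exc

    micro = None
    if config.get("weights"):
        try:
            series = msio.read_weight_stream(
                config["weights"], session_id=session_id, plate=plate
            )
            windows = events_to_exclusion_windows(
                events, (series.samples[0].t, series.samples[-1].t)
            )
            micro = summarize(series, windows, min_bite_g, artifact_budget)
            report.microstructure = micro.to_dict()
        except Exception as exc:
            raise StageError("microstructure", exc) from exc

    if gaze_rec is not None and config.get("aoi_timeline"):
        try:
            timeline = msio.read_aoi_timeline(config["aoi_timeline"])
            fixations = classify_fixations(gaze_rec, ivt)
            labeled = label_fixations(fixations, timeline, mode, marker_radius, mixed_dominance)
            t_last = gaze_rec.samples[-1].t if gaze_rec.samples else EARLY_WINDOW_S
            report.dwell_first_minute = _dwell_to_dict(
                dwell_summary(labeled, (0.0, EARLY_WINDOW_S))
            )
            report.dwell_full = _dwell_to_dict(
                dwell_summary(labeled, (0.0, max(t_last, EARLY_WINDOW_S)))
            )
        except Exception as exc:
            raise StageError("dwell", exc) from exc

    if events:
        try:
            comp = summarize_compliance(events)
            report.compliance = {
                "n": comp.n,
                "mean_dev_s": comp.mean_dev_s,
                "sd_dev_s": comp.sd_dev_s,
                "ci95": list(comp.ci95),
                "bins": comp.bins,
                "prop_within_1min": comp.prop_within_1min,
                "prop_within_2min": comp.prop_within_2min,
            }
            if micro is not None:
                durations = [
                    w.length_s
                    for w in events_to_exclusion_windows(
                        events, (0.0, micro.meal_duration_min * 60.0 + micro.excluded_s)
                    )
                ]
                report.compliance["meal_fraction_pct"] = meal_fraction(
                    durations, micro.meal_duration_min * 60.0 + micro.excluded_s
                )
        except Exception as exc:
            raise StageError("compliance", exc) from exc

    validity: dict[str, Any] = {}
    if report.qc is not None:
        validity["gaze_valid"] = bool(report.qc["passes"])
        validity["gaze_reason"] = (
            "" if report.qc["passes"] else f"gaze capture {report.qc['capture_pct']:.1f}% below threshold"
        )
    if micro is not None:
        ok = session_is_valid(micro, artifact_budget)
        validity["uem_valid"] = ok
        validity["uem_reason"] = (
            "" if ok else f"{len(micro.artifact_flags)} weight artifacts exceed budget {artifact_budget}"
        )
    report.validity = validity
    return report


def run_cohort(configs: list[dict[str, Any]]) -> dict[str, Any]:
    """Run many sessions; per-session errors are recorded, not fatal.

    Returns per-session rows plus a tally of invalid outputs by cause,
    mirroring cohort-level quality accounting.
    """
    if not configs:
        raise MealscopeError("empty cohort")
    rows = []
    tally = {"n_sessions": len(configs), "uem_invalid": 0, "gaze_invalid": 0, "errored": 0}
    for cfg in configs:
        try:
            rep = run_session(cfg)
        except Exception as exc:
            rows.append({"session_id": cfg.get("session_id", "?"), "error": str(exc)})
            tally["errored"] += 1
            continue
        row = {"session_id": rep.session_id, "plate": rep.plate}
        if rep.validity:
            if rep.validity.get("uem_valid") is False:
                tally["uem_invalid"] += 1
            if rep.validity.get("gaze_valid") is False:
                tally["gaze_invalid"] += 1
            row.update(rep.validity)
        if rep.microstructure:
            row.update(
                {
                    k: rep.microstructure[k]
                    for k in (
                        "meal_duration_min",
                        "mean_bite_g",
                        "eating_rate_g_min",
                        "deceleration_g_s2",
                    )
                }
            )
        rows.append(row)
    n = tally["n_sessions"]
    tally["uem_invalid_pct"] = 100.0 * tally["uem_invalid"] / n
    tally["gaze_invalid_pct"] = 100.0 * tally["gaze_invalid"] / n
    return {"sessions": rows, "tally": tally}
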