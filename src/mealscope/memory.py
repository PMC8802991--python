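"""Method-of-adjustment portion ladders and portion-recall scoring.

A portion ladder is the data contract behind an image-series adjustment task:
portions start at a one-tablespoon anchor and grow in fixed energy increments
(20 kcal by default, 5 kcal for low-energy-dense foods such as carrots) until
the plate is about 80 % full, capped at 110 images.  Recall accuracy compares
the portion a participant reconstructs from memory against the amount
actually served.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .datamodel import MealscopeError

MAX_STEPS = 110
DEFAULT_STEP_KCAL = 20.0
LOW_DENSITY_STEP_KCAL = 5.0


@dataclass(frozen=True)
class PortionStep:
    index: int
    grams: float
    kcal: float


@dataclass
class PortionSeries:
    food: str
    energy_density: float  # kcal/g
    start_g: float
    step_kcal: float
    steps: list[PortionStep]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "food": self.food,
            "energy_density": self.energy_density,
            "start_g": self.start_g,
            "step_kcal": self.step_kcal,
            "steps": [
                {"i": s.index, "grams": s.grams, "kcal": s.kcal} for s in self.steps
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PortionSeries":
        with open(path) as fh:
            payload = json.load(fh)
        steps = [
            PortionStep(index=s["i"], grams=s["grams"], kcal=s["kcal"])
            for s in payload["steps"]
        ]
        return cls(
            food=payload["food"],
            energy_density=payload["energy_density"],
            start_g=payload["start_g"],
            step_kcal=payload["step_kcal"],
            steps=steps,
        )


@dataclass(frozen=True)
class RecallScore:
    recalled_g: float
    actual_g: float
    pct_accuracy: float  # 100 * recalled / actual
    signed_pct_error: float  # pct_accuracy - 100


def build_series(
    food: str,
    energy_density: float,
    start_g: float,
    step_kcal: float = DEFAULT_STEP_KCAL,
    max_g: float | None = None,
    max_steps: int = MAX_STEPS,
) -> PortionSeries:
    """Build a portion ladder in exact ``step_kcal`` energy increments.

    Grams per step = step_kcal / energy_density.  The ladder is truncated at
    ``max_g`` (the ~80 %-plate-fill limit) and at ``max_steps`` images.  A
    ``max_g`` below the starting portion yields a single-step series.
    """
    if energy_density <= 0:
        raise MealscopeError("energy density must be positive")
    if start_g <= 0 or step_kcal <= 0:
        raise MealscopeError("start_g and step_kcal must be positive")
    step_g = step_kcal / energy_density
    steps: list[PortionStep] = []
    i = 0
    while len(steps) < max_steps:
        grams = start_g + i * step_g
        if max_g is not None and grams > max_g + 1e-9 and i > 0:
            break
        kcal = grams * energy_density
        steps.append(PortionStep(index=i, grams=round(grams, 9), kcal=round(kcal, 9)))
        if max_g is not None and grams >= max_g - 1e-9:
            break
        i += 1
    return PortionSeries(
        food=food,
        energy_density=energy_density,
        start_g=start_g,
        step_kcal=step_kcal,
        steps=steps,
    )


def nearest_step(series: PortionSeries, grams: float) -> PortionStep:
    """Ladder step closest in grams; ties resolve to the smaller index."""
    if not series.steps:
        raise MealscopeError("empty portion series")
    best = series.steps[0]
    best_d = abs(best.grams - grams)
    for step in series.steps[1:]:
        d = abs(step.grams - grams)
        if d < best_d - 1e-12:
            best, best_d = step, d
    return best


def score_recall(recalled_g: float, actual_g: float) -> RecallScore:
    """Recall accuracy as a ratio percentage plus a signed percent error."""
    if actual_g <= 0:
        raise MealscopeError("actual portion must be positive")
    if recalled_g < 0:
        raise MealscopeError("recalled portion must be >= 0")
    acc = 100.0 * recalled_g / actual_g
    return RecallScore(
        recalled_g=recalled_g,
        actual_g=actual_g,
        pct_accuracy=acc,
        signed_pct_error=acc - 100.0,
    )
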