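import numpy as np
import pytest

from mealscope.datamodel import (
    AOILabel,
    PlateCondition,
    RaterRow,
    RaterTable,
    WeightSample,
    WeightSeries,
)
from mealscope.io import load_rater_reliability_fixture
from mealscope.synthetic import square_plate_timeline


@pytest.fixture(scope="session")
def rater_fixture() -> RaterTable:
    """Packaged two-rater table: 14 AOI pairs across two videos."""
    return load_rater_reliability_fixture()


@pytest.fixture
def static_timeline():
    """Single-keyframe timeline with four rectangular AOIs."""
    return square_plate_timeline(n_keyframes=1)


def make_weight_series(weights, dt=2.0, session_id="s", plate=PlateCondition.CONTROL):
    samples = [WeightSample(t=i * dt, w=float(w)) for i, w in enumerate(weights)]
    return WeightSeries(session_id=session_id, plate=plate, samples=samples, nominal_dt=dt)


def random_rater_table(rng: np.random.Generator, k: int = 7) -> RaterTable:
    """Random valid table: one video, k AOIs, two noisy rater columns."""
    labels = [list(AOILabel)[i % len(list(AOILabel))] for i in range(k)]
    truth = rng.dirichlet(np.ones(k)) * 100.0
    rows = []
    cols = []
    for _ in range(2):
        col = np.clip(truth + rng.normal(0, 2.0, size=k), 0.01, None)
        cols.append(100.0 * col / col.sum())
    for i, lab in enumerate(labels):
        rows.append(
            RaterRow(aoi=lab, video_id="V", r1_pct=float(cols[0][i]), r2_pct=float(cols[1][i]))
        )
    return RaterTable(rows=rows)
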