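"""Dynamic AOI assignment, AGM recoding, and dwell summaries."""

import pytest

from mealscope.datamodel import AOIKeyframe, AOILabel, AOITimeline, Fixation, MealscopeError
from mealscope.aoi import (
    CodingMode,
    ForkInterval,
    assign_fixation,
    dwell_summary,
    label_fixations,
    polygons_at,
    recode_for_agm,
)


def rect(x0, y0, x1, y1):
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


def fix(t0, t1, x, y):
    return Fixation(t_start=t0, t_end=t1, x=x, y=y)


@pytest.fixture
def three_keyframes():
    square = {AOILabel.RICE: rect(0, 0, 100, 100)}
    return AOITimeline(
        keyframes=[AOIKeyframe(t=t, polygons=dict(square)) for t in (0, 10, 20)]
    )


class TestPolygonsAt:
    def test_step_function_latest_keyframe(self, three_keyframes):
        assert polygons_at(three_keyframes, 15) is three_keyframes.keyframes[1].polygons

    def test_left_closed_at_keyframe_time(self, three_keyframes):
        assert polygons_at(three_keyframes, 10) is three_keyframes.keyframes[1].polygons

    def test_single_keyframe_covers_all_later_times(self):
        tl = AOITimeline(keyframes=[AOIKeyframe(0, {AOILabel.RICE: rect(0, 0, 10, 10)})])
        assert polygons_at(tl, 5) is tl.keyframes[0].polygons

    def test_before_first_keyframe_is_error(self, three_keyframes):
        with pytest.raises(MealscopeError):
            polygons_at(three_keyframes, -1)


class TestAssignFixation:
    def test_marker_fully_inside_polygon(self):
        polys = {AOILabel.RICE: rect(0, 0, 200, 200)}
        label = assign_fixation(fix(0, 1, 100, 100), polys, CodingMode.MANUAL, 20)
        assert label is AOILabel.RICE

    def test_dominant_overlap_wins_in_manual_mode(self):
        # marker centred 10 px inside the rice side of a shared border:
        # roughly 70/30 split in favour of rice -> rice (dominance > 60 %)
        polys = {
            AOILabel.RICE: rect(0, 0, 110, 200),
            AOILabel.MEATBALLS: rect(110, 0, 220, 200),
        }
        label = assign_fixation(fix(0, 1, 100, 100), polys, CodingMode.MANUAL, 20)
        assert label is AOILabel.RICE

    def test_even_split_is_mixed_in_manual_mode(self):
        polys = {
            AOILabel.RICE: rect(0, 0, 100, 200),
            AOILabel.MEATBALLS: rect(100, 0, 200, 200),
        }
        label = assign_fixation(fix(0, 1, 100, 100), polys, CodingMode.MANUAL, 20)
        assert label is AOILabel.MIXED

    def test_even_split_ties_to_rice_in_agm_mode(self):
        polys = {
            AOILabel.RICE: rect(0, 0, 100, 200),
            AOILabel.MEATBALLS: rect(100, 0, 200, 200),
        }
        label = assign_fixation(fix(0, 1, 100, 100), polys, CodingMode.AGM_COMPATIBLE, 20)
        assert label is AOILabel.RICE

    def test_no_overlap_is_none(self):
        polys = {AOILabel.RICE: rect(0, 0, 10, 10)}
        assert assign_fixation(fix(0, 1, 500, 500), polys, CodingMode.MANUAL, 20) is AOILabel.NONE

    def test_agm_mode_never_emits_mixed_or_manual_only_labels(self):
        polys = {
            AOILabel.EMPTY: rect(0, 0, 200, 200),  # manual-only label
            AOILabel.BREAD: rect(0, 0, 200, 200),
        }
        label = assign_fixation(fix(0, 1, 100, 100), polys, CodingMode.AGM_COMPATIBLE, 20)
        assert label is AOILabel.NONE

    def test_empty_polygon_map_is_error(self):
        with pytest.raises(MealscopeError):
            assign_fixation(fix(0, 1, 0, 0), {}, CodingMode.MANUAL, 20)


class TestRecodeForAGM:
    def test_fork_interval_takes_backing_label(self):
        labeled = [(fix(1, 2, 0, 0), AOILabel.BORDER)]
        out = recode_for_agm(labeled, [ForkInterval(0.5, 3.0, AOILabel.RICE)])
        assert out[0][1] is AOILabel.RICE

    def test_mixed_recodes_to_declared_label(self):
        labeled = [(fix(1, 2, 0, 0), AOILabel.MIXED)]
        out = recode_for_agm(labeled, mixed_recode=AOILabel.VEGETABLES)
        assert out[0][1] is AOILabel.VEGETABLES

    def test_identity_without_fork_or_mixed(self):
        labeled = [(fix(1, 2, 0, 0), AOILabel.RICE), (fix(3, 4, 0, 0), AOILabel.BORDER)]
        assert recode_for_agm(labeled) == labeled

    def test_fork_interval_without_backing_is_error(self):
        with pytest.raises(MealscopeError):
            recode_for_agm([], [ForkInterval(0, 1, None)])


class TestDwellSummary:
    def test_proportions(self):
        labeled = [
            (fix(0, 3, 0, 0), AOILabel.RICE),
            (fix(4, 5, 0, 0), AOILabel.MEATBALLS),
        ]
        s = dwell_summary(labeled, (0, 10))
        assert s.proportional_pct[AOILabel.RICE] == pytest.approx(75.0)
        assert s.proportional_pct[AOILabel.MEATBALLS] == pytest.approx(25.0)

    def test_window_clipping(self):
        labeled = [(fix(58, 63, 0, 0), AOILabel.RICE)]
        s = dwell_summary(labeled, (0, 60))
        assert s.dwell_s[AOILabel.RICE] == pytest.approx(2.0)

    def test_empty_window_is_error(self):
        with pytest.raises(MealscopeError):
            dwell_summary([], (10, 10))

    def test_normalization_to_machine_precision(self):
        labeled = [
            (fix(i, i + 0.37, 0, 0), lab)
            for i, lab in enumerate(
                [AOILabel.RICE, AOILabel.VEGETABLES, AOILabel.MEATBALLS, AOILabel.BORDER] * 5
            )
        ]
        s = dwell_summary(labeled, (0, 30))
        assert sum(s.proportional_pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_shrinking_window_never_increases_dwell(self):
        labeled = [
            (fix(0, 5, 0, 0), AOILabel.RICE),
            (fix(6, 12, 0, 0), AOILabel.VEGETABLES),
            (fix(13, 30, 0, 0), AOILabel.RICE),
        ]
        wide = dwell_summary(labeled, (0, 30))
        narrow = dwell_summary(labeled, (2, 14))
        for lab in wide.dwell_s:
            assert narrow.dwell_s.get(lab, 0.0) <= wide.dwell_s[lab] + 1e-12


class TestModeConservation:
    def test_total_dwell_conserved_between_manual_and_agm(self, static_timeline):
        # fixations straddling AOI borders so manual coding produces `mixed`
        polys = static_timeline.keyframes[0].polygons
        fixes = []
        t = 0.0
        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(40):
            x = float(rng.uniform(150, 1750))
            y = float(rng.uniform(80, 1000))
            fixes.append(fix(t, t + 0.3, x, y))
            t += 0.4
        manual = label_fixations(fixes, static_timeline, CodingMode.MANUAL)
        agm = label_fixations(fixes, static_timeline, CodingMode.AGM_COMPATIBLE)
        window = (0.0, t)
        food = [AOILabel.RICE, AOILabel.VEGETABLES, AOILabel.MEATBALLS, AOILabel.BORDER]
        m = dwell_summary(manual, window, include_labels=food + [AOILabel.MIXED])
        a = dwell_summary(agm, window, include_labels=food)
        # AGM redistributes mixed mass onto single AOIs: per-label dwell can
        # only grow, and the total over labelled AOIs is conserved
        for lab in food:
            assert a.dwell_s[lab] >= m.dwell_s[lab] - 1e-12
        landed_manual = [
            (f, lab) for f, lab in manual if lab is not AOILabel.NONE
        ]
        landed_agm = [(f, lab) for f, lab in agm if lab is not AOILabel.NONE]
        if len(landed_manual) == len(landed_agm):
            assert a.total_aoi_s == pytest.approx(m.total_aoi_s, abs=1e-9)

    def test_agm_partition_property(self, static_timeline):
        import numpy as np

        rng = np.random.default_rng(9)
        allowed = {
            AOILabel.RICE,
            AOILabel.VEGETABLES,
            AOILabel.MEATBALLS,
            AOILabel.BORDER,
            AOILabel.NONE,
        }
        for i in range(50):
            f = fix(i, i + 0.2, float(rng.uniform(0, 1920)), float(rng.uniform(0, 1080)))
            label = assign_fixation(
                f, static_timeline.keyframes[0].polygons, CodingMode.AGM_COMPATIBLE, 20
            )
            assert label in allowed
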