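"""Geometry, per-frame masks and bout segmentation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from norkit import (
    FrameMask,
    LandmarkMode,
    ObjectSpec,
    brute_force_events,
    default_modes,
    distance_to_object,
    frame_mask,
    head_direction,
    is_oriented,
    segment_events,
)
from norkit.preprocess import preprocess
from norkit.synthetic import random_script, simulate_session

from conftest import make_recording, parked_head


class TestDistanceToObject:
    OBJ = ObjectSpec(id="o", role="novel", center_cm=(0.0, 0.0), footprint_radius_cm=2.0)

    def test_interior_clamps_to_zero(self):
        assert distance_to_object((0.0, 0.0), self.OBJ) == 0.0

    def test_distance_measured_from_footprint_boundary(self):
        assert distance_to_object((5.0, 0.0), self.OBJ) == pytest.approx(3.0)

    def test_point_on_footprint_circle_is_zero(self):
        assert distance_to_object((2.0, 0.0), self.OBJ) == 0.0


class TestHeadDirection:
    def test_symmetric_ears_point_toward_nose(self):
        assert head_direction((0, 1), (-1, 0), (1, 0)) == pytest.approx((0.0, 1.0))

    def test_offset_triangle_normalizes(self):
        # ear midpoint (0,1); nose-midpoint vector (3,0) -> unit (1,0)
        assert head_direction((3, 1), (0, 0), (0, 2)) == pytest.approx((1.0, 0.0))

    def test_nose_at_ear_midpoint_is_undefined(self):
        assert head_direction((0.0, 1.0), (-1.0, 1.0), (1.0, 1.0)) is None


class TestIsOriented:
    OBJ = ObjectSpec(id="o", role="novel", center_cm=(0.0, 5.0), footprint_radius_cm=1.0)

    def test_zero_angle_passes(self):
        assert is_oriented((0, 1), (0, 1), self.OBJ, 45.0)

    def test_right_angle_fails_at_45(self):
        side = ObjectSpec(id="o", role="novel", center_cm=(5.0, 1.0), footprint_radius_cm=1.0)
        assert not is_oriented((0, 1), (0, 1), side, 45.0)

    def test_nose_inside_footprint_always_passes(self):
        assert is_oriented((0.0, 4.5), (0.0, -1.0), self.OBJ, 45.0)

    def test_boundary_angle_passes(self):
        d = (math.cos(math.radians(45)), math.sin(math.radians(45)))
        east = ObjectSpec(id="o", role="novel", center_cm=(10.0, 0.0), footprint_radius_cm=0.0)
        assert is_oriented((0.0, 0.0), d, east, 45.0)


class TestFrameMask:
    def test_far_field_mouse_gives_all_false_masks(self, config):
        rec = make_recording(parked_head(30, nose_at=(25.0, 45.0), facing=(1.0, 0.0)))
        for mode in default_modes(config):
            for obj in config.objects:
                assert not frame_mask(rec, obj, mode, config).bits.any()

    def test_graded_thresholds_at_1p2_cm(self, config):
        # nose held oriented at 1.2 cm from the novel footprint
        obj = config.novel
        nose = (obj.center_cm[0] + obj.footprint_radius_cm + 1.2, obj.center_cm[1])
        rec = make_recording(parked_head(10, nose_at=nose, facing=(-1.0, 0.0)))
        bits = {
            t: frame_mask(rec, obj, LandmarkMode("NT", t), config).bits
            for t in (1.0, 1.5, 2.0)
        }
        assert not bits[1.0].any()
        assert bits[1.5].all()
        assert bits[2.0].all()

    def test_orientation_gate_rejects_sideways_head(self, config):
        obj = config.novel
        nose = (obj.center_cm[0] + obj.footprint_radius_cm + 1.0, obj.center_cm[1])
        facing_away = make_recording(parked_head(10, nose_at=nose, facing=(0.0, 1.0)))
        m = frame_mask(facing_away, obj, LandmarkMode("NT", 2.0), config)
        assert not m.bits.any()

    def test_combined_mode_is_framewise_and_of_nt2_and_bc2(self, config):
        rng = np.random.default_rng(12)
        script = random_script(rng, config, length_s=60, seed=5)
        rec, _ = simulate_session(script, config, length_s=60, fps=30)
        track = preprocess(rec, config)
        for obj in config.objects:
            nt = frame_mask(track, obj, LandmarkMode("NT", 2.0), config).bits
            bc = frame_mask(track, obj, LandmarkMode("BC"), config).bits
            both = frame_mask(track, obj, LandmarkMode("NT_BC"), config).bits
            np.testing.assert_array_equal(both, nt & bc)

    def test_invalid_landmark_frames_are_false(self, config):
        obj = config.novel
        nose = (obj.center_cm[0] + obj.footprint_radius_cm + 0.5, obj.center_cm[1])
        rec = make_recording(parked_head(6, nose_at=nose, facing=(-1.0, 0.0)))
        rec.x[2, 0] = np.nan  # nose missing at frame 2
        rec.y[2, 0] = np.nan
        rec.x[4, 1] = np.nan  # left ear missing at frame 4
        rec.y[4, 1] = np.nan
        bits = frame_mask(rec, obj, LandmarkMode("NT", 2.0), config).bits
        assert not bits[2] and not bits[4]
        assert bits[[0, 1, 3, 5]].all()

    def test_unconfigured_threshold_is_an_error(self, config):
        rec = make_recording(parked_head(3, nose_at=(25.0, 45.0), facing=(1.0, 0.0)))
        with pytest.raises(ValueError, match="threshold"):
            frame_mask(rec, config.novel, LandmarkMode("NT", 0.7), config)


def _mask(bits):
    return FrameMask(mode=LandmarkMode("NT", 2.0), object_id="A",
                     bits=np.asarray(bits, dtype=bool))


class TestSegmentEvents:
    def test_all_false_yields_no_events(self):
        assert segment_events(_mask([False] * 50), 30, 0.1, 0.2) == []

    def test_short_gap_merges_into_one_event(self):
        # T T F F T T at 30 fps, merge gap 0.1 s (3 frames): merged, 6 frames
        ev = segment_events(_mask([1, 1, 0, 0, 1, 1]), 30, 0.0, 0.1)
        assert len(ev) == 1
        assert (ev[0].start_frame, ev[0].end_frame) == (0, 5)
        assert ev[0].duration_s == pytest.approx(0.2)

    def test_isolated_frame_shorter_than_min_bout_discarded(self):
        ev = segment_events(_mask([0, 0, 1, 0, 0]), 30, 0.1, 0.0)
        assert ev == []

    def test_exact_min_bout_duration_kept(self):
        ev = segment_events(_mask([0, 1, 1, 1, 0]), 30, 0.1, 0.0)
        assert len(ev) == 1 and ev[0].duration_s == pytest.approx(0.1)

    def test_gap_wider_than_merge_window_stays_split(self):
        ev = segment_events(_mask([1, 1, 0, 0, 0, 0, 1, 1]), 30, 0.0, 0.1)
        assert len(ev) == 2

    def test_all_true_is_one_event_spanning_session(self):
        ev = segment_events(_mask([True] * 40), 30, 0.1, 0.2)
        assert len(ev) == 1
        assert (ev[0].start_frame, ev[0].end_frame) == (0, 39)


@settings(derandomize=True, max_examples=300, deadline=None)
@given(
    bits=st.lists(st.booleans(), min_size=1, max_size=200),
    min_bout=st.floats(0.0, 0.3),
    merge_gap=st.floats(0.0, 0.3),
)
def test_segmentation_matches_brute_force_enumeration(bits, min_bout, merge_gap):
    """The vectorized segmenter agrees with naive frame-by-frame enumeration."""
    m = _mask(bits)
    fast = segment_events(m, 30.0, min_bout, merge_gap)
    slow = brute_force_events(m, 30.0, min_bout, merge_gap)
    assert [(e.start_frame, e.end_frame) for e in fast] == [
        (e.start_frame, e.end_frame) for e in slow
    ]


def test_events_are_disjoint_and_separated(config):
    rng = np.random.default_rng(2)
    bits = rng.random(500) < 0.4
    ev = segment_events(_mask(bits), 30.0, 0.1, 0.2)
    for a, b in zip(ev, ev[1:]):
        assert a.end_frame < b.start_frame
        assert (b.start_frame - a.end_frame - 1) / 30.0 > 0.2
    for e in ev:
        assert e.duration_s >= 0.1 - 1e-9


class TestMaskNesting:
    def test_threshold_nesting_and_mode_subsets_on_simulated_session(self, config):
        rng = np.random.default_rng(7)
        script = random_script(rng, config, length_s=120, seed=8)
        rec, _ = simulate_session(script, config, length_s=120, fps=30)
        track = preprocess(rec, config)
        for obj in config.objects:
            nt = {t: frame_mask(track, obj, LandmarkMode("NT", t), config).bits
                  for t in config.thresholds_cm}
            assert not (nt[1.0] & ~nt[1.5]).any()
            assert not (nt[1.5] & ~nt[2.0]).any()
            touch = frame_mask(track, obj, LandmarkMode("TOUCH"), config).bits
            assert not (touch & ~nt[1.0]).any()
            ntbc = frame_mask(track, obj, LandmarkMode("NT_BC"), config).bits
            bc = frame_mask(track, obj, LandmarkMode("BC"), config).bits
            assert not (ntbc & ~(nt[2.0] & bc)).any()

    def test_disjoint_object_zones_make_nt_masks_mutually_exclusive(self, config):
        rng = np.random.default_rng(17)
        script = random_script(rng, config, length_s=120, seed=18)
        rec, _ = simulate_session(script, config, length_s=120, fps=30)
        track = preprocess(rec, config)
        for t in config.thresholds_cm:
            a = frame_mask(track, config.novel, LandmarkMode("NT", t), config).bits
            b = frame_mask(track, config.familiar, LandmarkMode("NT", t), config).bits
            assert not (a & b).any()


def test_default_modes_enumerate_six(config):
    modes = default_modes(config)
    assert [m.label for m in modes] == ["NT1", "NT1.5", "NT2", "BC2", "NTBC2", "Touch"]
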