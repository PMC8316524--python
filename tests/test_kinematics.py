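"""Kinematics pipeline: auxiliary points, alignment, events, cycles, flattening."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaituniq.anatomy import POINT_INDEX, SegmentSet, Segment, DEFAULT_SEGMENTS
from gaituniq.kinematics import (
    GAIT_VECTOR_LEN,
    KinematicsError,
    PointFrameSeries,
    align_to_lab,
    build_gait_vector,
    derive_auxiliary_points,
    detect_heel_strikes,
    extract_cycles,
    resample_cycle,
    segment_orientations,
    spatiotemporal_params,
    trial_to_cycles,
    unflatten_gait_vector,
)


def make_series(positions, frame_rate=120.0):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions)) / frame_rate
    return PointFrameSeries(frame_rate, times, positions)


def walking_series(direction=(1.0, 0.0), n_frames=400, frame_rate=120.0,
                   heel_period=1.03):
    """A minimal synthetic walker: hips translate, heel bounces."""
    t = np.arange(n_frames) / frame_rate
    pos = np.zeros((n_frames, 17, 3))
    pos[:, :, 2] = 1.0
    # distinct static offset per point so no segment is degenerate
    pos += (np.arange(17)[:, None] * np.array([0.011, 0.017, 0.023]))[None]
    dx, dy = direction
    for lab, off in (("l_hip", +0.1), ("r_hip", -0.1)):
        pos[:, POINT_INDEX[lab], 0] = 1.2 * dx * t - off * dy
        pos[:, POINT_INDEX[lab], 1] = 1.2 * dy * t + off * dx
    heel = 0.05 * (1 - np.cos(2 * np.pi * t / heel_period)) + 0.03
    pos[:, POINT_INDEX["r_heel"], 2] = heel
    pos[:, POINT_INDEX["r_heel"], 0] = pos[:, POINT_INDEX["r_hip"], 0]
    return make_series(pos, frame_rate)


class TestSegmentSet:
    def test_canonical_set_is_valid(self):
        assert len(SegmentSet()) == 16

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="16"):
            SegmentSet(DEFAULT_SEGMENTS[:15])

    def test_uncovered_point_rejected(self):
        bad = DEFAULT_SEGMENTS[:15] + (Segment("dup", "l_hip", "l_knee"),)
        with pytest.raises(ValueError, match="no segment"):
            SegmentSet(bad)


class TestAuxiliaryPoints:
    @pytest.mark.parametrize("l, r, mid", [
        ((-0.1, 0, 1.0), (0.1, 0, 1.0), (0, 0, 1.0)),
        ((1, 2, 3), (3, 4, 5), (2, 3, 4)),
        ((0.3, -0.2, 0.9), (0.3, -0.2, 0.9), (0.3, -0.2, 0.9)),
    ])
    def test_midpoints(self, l, r, mid):
        pos = np.zeros((17, 3))
        pos[POINT_INDEX["l_hip"]] = l
        pos[POINT_INDEX["r_hip"]] = r
        pos[POINT_INDEX["l_shoulder"]] = l
        pos[POINT_INDEX["r_shoulder"]] = r
        aug = derive_auxiliary_points(pos)
        assert aug.shape == (19, 3)
        np.testing.assert_allclose(aug[17], mid)   # mid_hip
        np.testing.assert_allclose(aug[18], mid)   # mid_shoulder

    def test_bad_shape_rejected(self):
        with pytest.raises(KinematicsError):
            derive_auxiliary_points(np.zeros((16, 3)))


class TestAlignToLab:
    def test_y_walker_rotated_onto_x(self):
        s = align_to_lab(walking_series(direction=(0.0, 1.0)))
        hip = 0.5 * (s.point("l_hip") + s.point("r_hip"))
        disp = hip[-1] - hip[0]
        assert disp[0] > 0
        assert abs(disp[1]) < 1e-9
        np.testing.assert_allclose(s.positions[:, :, 2],
                                   walking_series((0.0, 1.0)).positions[:, :, 2])

    def test_already_aligned_is_identity(self):
        raw = walking_series(direction=(1.0, 0.0))
        s = align_to_lab(raw)
        np.testing.assert_allclose(s.positions, raw.positions, atol=1e-9)

    def test_backward_walker_flipped(self):
        raw = walking_series(direction=(-1.0, 0.0))
        s = align_to_lab(raw)
        np.testing.assert_allclose(s.positions[:, :, 0], -raw.positions[:, :, 0],
                                   atol=1e-9)
        np.testing.assert_allclose(s.positions[:, :, 1], -raw.positions[:, :, 1],
                                   atol=1e-9)

    def test_no_progression_rejected(self):
        pos = np.zeros((200, 17, 3))
        pos[:, :, 2] = 1.0
        with pytest.raises(KinematicsError, match="progression"):
            align_to_lab(make_series(pos))


class TestHeelStrikes:
    def test_analytic_cosine_minima(self):
        s = walking_series(n_frames=360)
        events = detect_heel_strikes(s, "right")
        expected = np.array([0.0, 1.03, 2.06])
        assert len(events) == 3
        assert np.all(np.abs(s.times[events] - expected) <= 1.0 / 120 + 1e-9)

    def test_constant_heel_rejected(self):
        pos = np.zeros((240, 17, 3))
        pos[:, :, 2] = 1.0
        pos[:, POINT_INDEX["r_hip"], 0] = np.arange(240) / 120.0
        pos[:, POINT_INDEX["l_hip"], 0] = np.arange(240) / 120.0
        with pytest.raises(KinematicsError, match="constant"):
            detect_heel_strikes(make_series(pos), "right")

    def test_two_minima_give_one_cycle(self):
        s = walking_series(n_frames=190)   # ~1.58 s: strikes at 0 and 1.03 only
        events = detect_heel_strikes(s, "right")
        assert len(events) == 2
        assert len(extract_cycles(s, events)) == 1

    def test_cycle_count_is_events_minus_one(self, small_cohort):
        _, trials, _ = small_cohort
        series = align_to_lab(trials[("S0003", "T1")])
        events = detect_heel_strikes(series, "right")
        assert len(extract_cycles(series, events)) == len(events) - 1

    def test_short_series_rejected(self):
        with pytest.raises(KinematicsError, match="1 s"):
            detect_heel_strikes(walking_series(n_frames=60), "right")


class TestExtractCycles:
    def _series_with_segment(self, prox_xyz, dist_xyz):
        pos = np.tile(np.arange(17)[None, :, None] * [[0.01, 0.02, 0.03]], (130, 1, 1))
        pos = pos + np.linspace(0, 1, 130)[:, None, None] * 0.001
        pos[:, POINT_INDEX["l_knee"]] = prox_xyz
        pos[:, POINT_INDEX["l_ankle"]] = dist_xyz
        return make_series(pos)

    @pytest.mark.parametrize("prox, dist, expected", [
        ((0, 0, 0), (0, 0, 2), (0, 0, 1)),
        ((0, 0, 0), (3, 4, 0), (0.6, 0.8, 0)),
    ])
    def test_direction_cosines(self, prox, dist, expected):
        s = self._series_with_segment(prox, dist)
        orient = segment_orientations(s.positions, SegmentSet())
        shank_idx = SegmentSet().names.index("l_shank")
        np.testing.assert_allclose(orient[:, shank_idx, :],
                                   np.tile(expected, (130, 1)), atol=1e-12)

    def test_degenerate_segment_rejected(self):
        s = self._series_with_segment((1, 1, 1), (1, 1, 1))
        with pytest.raises(KinematicsError, match="degenerate"):
            segment_orientations(s.positions, SegmentSet())

    def test_too_few_events_rejected(self, small_cohort):
        _, trials, _ = small_cohort
        with pytest.raises(KinematicsError, match="2 events"):
            extract_cycles(trials[("S0001", "T1")], [10])


class TestResample:
    def test_identity_on_101_frames(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((101, 16, 3))
        raw /= np.linalg.norm(raw, axis=-1, keepdims=True)
        out = resample_cycle(raw)
        np.testing.assert_allclose(out, raw, atol=1e-12)

    def test_linear_ramp_channel(self):
        F = 61
        raw = np.zeros((F, 16, 3))
        raw[:, :, 2] = 1.0
        raw[:, 0, 0] = np.linspace(0.0, 1.0, F)
        out = resample_cycle(raw, renormalize=False)
        np.testing.assert_allclose(out[:, 0, 0], np.arange(101) / 100, atol=1e-12)

    def test_midpoint_renormalised(self):
        raw = np.zeros((2, 16, 3))
        raw[0, :, 0] = 1.0
        raw[1, :, 1] = 1.0
        out = resample_cycle(raw, target_frames=3)
        np.testing.assert_allclose(out[1, 0], [np.sqrt(2) / 2, np.sqrt(2) / 2, 0.0],
                                   atol=1e-12)

    def test_single_frame_rejected(self):
        with pytest.raises(KinematicsError):
            resample_cycle(np.ones((1, 16, 3)))


class TestGaitVector:
    def test_length_4848(self, small_vectors):
        vectors, _ = small_vectors
        assert vectors.shape[1] == GAIT_VECTOR_LEN == 16 * 3 * 101

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_flatten_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        orient = rng.standard_normal((101, 16, 3))
        orient /= np.linalg.norm(orient, axis=-1, keepdims=True)
        vec = build_gait_vector(orient)
        assert vec.shape == (GAIT_VECTOR_LEN,)
        np.testing.assert_array_equal(unflatten_gait_vector(vec), orient)

    def test_constant_up_block_pattern(self):
        orient = np.zeros((101, 16, 3))
        orient[:, :, 2] = 1.0
        vec = build_gait_vector(orient)
        blocks = vec.reshape(16, 3, 101)
        assert np.all(blocks[:, 2, :] == 1.0)
        assert np.all(blocks[:, :2, :] == 0.0)


class TestSpatiotemporal:
    def test_cadence_and_velocity(self):
        s = walking_series(heel_period=1.0, n_frames=250)
        events = detect_heel_strikes(s, "right")
        st_ = spatiotemporal_params(s, events[:2])
        assert st_.cadence == pytest.approx(120.0, rel=1e-6)
        assert st_.velocity == pytest.approx(1.2, rel=1e-6)
        assert st_.step_length == pytest.approx(0.6, rel=1e-6)

    def test_too_few_events_rejected(self):
        with pytest.raises(KinematicsError):
            spatiotemporal_params(walking_series(), [5])


class TestPipelineInvariants:
    def test_unit_norm_everywhere(self, small_cohort):
        _, trials, _ = small_cohort
        for key in [("S0001", "T1"), ("S0005", "T2")]:
            for c in trial_to_cycles(trials[key], max_cycles=2):
                norms = np.linalg.norm(c.orientations, axis=-1)
                assert np.abs(norms - 1.0).max() <= 1e-9

    def test_rotation_equivariance(self, small_cohort):
        _, trials, _ = small_cohort
        series = trials[("S0002", "T1")]
        theta = 1.3
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        rotated = PointFrameSeries(series.frame_rate, series.times.copy(),
                                   series.positions @ rot.T)
        v0 = [build_gait_vector(cy.orientations)
              for cy in trial_to_cycles(series, max_cycles=2)]
        v1 = [build_gait_vector(cy.orientations)
              for cy in trial_to_cycles(rotated, max_cycles=2)]
        np.testing.assert_allclose(v0, v1, atol=1e-9)
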