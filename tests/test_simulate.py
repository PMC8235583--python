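"""Synthetic-data generator: cohort sampling, MET model, kinematics."""

import numpy as np
import pytest

import kinemet as km
from kinemet.simulate import METTrace, _subject_offset


class TestSampleCohort:
    def test_degenerate_sds_reproduce_means_exactly(self):
        params = km.CohortParams(age_sd=0.0, weight_sd=0.0, body_fat_sd=0.0)
        cohort = km.sample_cohort(5, params, seed=3)
        for s in cohort:
            assert (s.age, s.weight, s.body_fat) == (21.90, 60.20, 20.69)

    def test_sex_split_configurable_to_10_male_11_female(self):
        cohort = km.sample_cohort(21, seed=0, n_male=10)
        sexes = [s.sex for s in cohort]
        assert sexes.count("male") == 10 and sexes.count("female") == 11

    def test_large_sample_mean_weight_converges(self):
        cohort = km.sample_cohort(10_000, seed=11)
        mean_w = np.mean([s.weight for s in cohort])
        assert abs(mean_w - 60.20) < 3 * 7.60 / np.sqrt(10_000)

    def test_deterministic_for_fixed_seed(self):
        a = km.sample_cohort(8, seed=42)
        b = km.sample_cohort(8, seed=42)
        assert all(x == y for x, y in zip(a, b))

    @pytest.mark.parametrize("bad", [0, -3])
    def test_nonpositive_n_rejected(self, bad):
        with pytest.raises(ValueError):
            km.sample_cohort(bad)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            km.CohortParams(weight_sd=-1.0)


class TestMETGroundTruth:
    def test_standing_base_met_without_subject(self):
        assert km.met_ground_truth("standing", 0.0) == pytest.approx(1.3)

    def test_walking_met_increases_with_speed(self):
        assert km.met_ground_truth("walking", 6.4) > km.met_ground_truth("walking", 4.8)

    def test_running_exceeds_walking_even_at_lower_speed_gap(self):
        assert km.met_ground_truth("running", 8.0) > km.met_ground_truth("walking", 6.4)

    def test_activity_ordering_holds_per_subject(self):
        for s in km.sample_cohort(10, seed=5):
            stand = km.met_ground_truth("standing", 0.0, s)
            walks = [km.met_ground_truth("walking", v, s) for v in (4.8, 5.6, 6.4)]
            runs = [km.met_ground_truth("running", v, s) for v in (8.0, 8.3)]
            assert stand < min(walks) and max(walks) < min(runs)

    def test_subject_offset_is_stable_across_calls(self, subject):
        a = km.met_ground_truth("walking", 4.8, subject)
        b = km.met_ground_truth("walking", 4.8, subject)
        assert a == b

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            km.met_ground_truth("walking", -1.0)

    def test_offset_sd_zero_gives_base_value(self, subject):
        params = km.METParams(subject_effect_sd=0.0)
        assert km.met_ground_truth("standing", 0.0, subject, params) == pytest.approx(1.3)
        assert _subject_offset(subject, params) == 0.0


class TestActivityBout:
    def test_standing_with_speed_rejected(self):
        with pytest.raises(ValueError):
            km.ActivityBout("standing", 4.8)

    def test_intensity_mapping(self):
        assert km.ActivityBout("standing", 0.0).intensity == "light"
        assert km.ActivityBout("walking", 4.8).intensity == "moderate"
        assert km.ActivityBout("running", 8.0).intensity == "vigorous"


class TestGenerateSequence:
    def test_five_minute_bout_at_30hz_has_9000_frames(self, subject, side_view):
        bout = km.ActivityBout("walking", 4.8, duration=5.0)
        seq, _ = km.generate_sequence(subject, bout, side_view, seed=0)
        assert len(seq) == 9000

    def test_noiseless_standing_is_a_static_pose(self, subject, side_view):
        params = km.MotionParams(sway_sd=0.0, drift_amplitude=0.0, sensor_noise_sd=0.0)
        bout = km.ActivityBout("standing", 0.0, duration=0.2)
        seq, _ = km.generate_sequence(subject, bout, side_view, params, seed=0)
        assert np.allclose(seq.positions, seq.positions[0])

    def test_cadence_recoverable_from_ankle_spectrum(self, subject, side_view, noiseless_params):
        bout = km.ActivityBout("walking", 4.8, duration=1.0)
        seq, _ = km.generate_sequence(subject, bout, side_view, noiseless_params, seed=1)
        y = seq.joint("ANKLE_LEFT")[:, 1]
        y = y - y.mean()
        freqs = np.fft.rfftfreq(len(y), d=1.0 / noiseless_params.frame_rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y)))]
        expected = noiseless_params.cadence(4.8)
        assert abs(peak - expected) <= freqs[1]  # within one frequency bin

    def test_bit_identical_for_fixed_seed(self, subject, walk_bout, side_view):
        s1, t1 = km.generate_sequence(subject, walk_bout, side_view, seed=9)
        s2, t2 = km.generate_sequence(subject, walk_bout, side_view, seed=9)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(t1.met_values, t2.met_values)

    def test_views_share_motion_and_trace(self, subject, walk_bout, noiseless_params):
        side, rear = km.CANONICAL_VIEWS[0], km.CANONICAL_VIEWS[2]
        s_side, t_side = km.generate_sequence(subject, walk_bout, side, noiseless_params, seed=4)
        s_rear, t_rear = km.generate_sequence(subject, walk_bout, rear, noiseless_params, seed=4)
        assert np.array_equal(t_side.met_values, t_rear.met_values)
        # same inter-joint geometry frame by frame (rigid view change only)
        d_side = np.linalg.norm(s_side.positions[:, 0] - s_side.positions[:, 14], axis=1)
        d_rear = np.linalg.norm(s_rear.positions[:, 0] - s_rear.positions[:, 14], axis=1)
        assert np.allclose(d_side, d_rear)

    def test_met_trace_sampled_at_breath_interval(self, subject, walk_bout, side_view):
        _, trace = km.generate_sequence(subject, walk_bout, side_view, seed=0)
        assert np.allclose(np.diff(trace.timestamps), km.METParams().breath_interval)


class TestProjectToView:
    def test_zero_yaw_is_translation_only(self, subject, walk_bout, noiseless_params):
        world, _ = km.generate_bout(subject, walk_bout, noiseless_params, seed=0)
        rear = km.CameraView("rear", yaw=0.0, height=0.9, standoff=2.0)
        proj = km.project_to_view(world, rear)
        shift = np.array([0.0, -0.9, 2.0])
        assert np.allclose(proj.positions, world.positions + shift)

    def test_90_degree_yaw_maps_foreaft_to_lateral(self):
        view = km.CameraView("side", yaw=90.0, height=0.9, standoff=2.0)
        seq = km.SkeletonSequence(
            timestamps=[0.0],
            joint_names=("P",),
            positions=[[[0.0, 0.0, 1.0]]],  # one unit along world fore-aft
        )
        proj = km.project_to_view(seq, view)
        assert np.allclose(proj.positions[0, 0], [1.0, -0.9, 2.0])

    def test_pairwise_distances_preserved_under_any_yaw(self, subject, walk_bout):
        world, _ = km.generate_bout(subject, walk_bout, seed=2)
        proj = km.project_to_view(world, km.CameraView("oblique", yaw=37.0))
        p0, q0 = world.positions[:, 3], world.positions[:, 14]
        p1, q1 = proj.positions[:, 3], proj.positions[:, 14]
        assert np.allclose(
            np.linalg.norm(p0 - q0, axis=1), np.linalg.norm(p1 - q1, axis=1)
        )


class TestProtocol:
    def test_hierarchical_seeding_is_stable_when_bouts_are_added(self, subject):
        base = km.Protocol().scaled(n_subjects=1, duration=0.2)
        extended = km.Protocol(
            n_subjects=1,
            bouts=base.bouts + (km.ActivityBout("walking", 5.0, 0.2),),
        )
        a = km.simulate_protocol(base, seed=5)
        b = km.simulate_protocol(extended, seed=5)
        assert np.array_equal(a[0].sequence.positions, b[0].sequence.positions)

    def test_trace_values_positive_and_increasing_time(self, subject, walk_bout, side_view):
        _, trace = km.generate_sequence(subject, walk_bout, side_view, seed=0)
        assert np.all(trace.met_values > 0)
        assert np.all(np.diff(trace.timestamps) > 0)

    def test_trace_rejects_nonpositive_met(self):
        with pytest.raises(ValueError):
            METTrace(timestamps=[0.0, 1.0], met_values=[1.0, 0.0])
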