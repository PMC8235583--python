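"""Joint selection, finite-difference velocities, PCA retention rule."""

import numpy as np
import pytest

import kinemet as km
from kinemet.features import (
    SELECTED_JOINTS,
    FeatureMatrix,
    apply_pca,
    fit_pca,
    select_joints,
    velocities,
)
from kinemet.sequence import SkeletonSequence


def _seq(positions, timestamps=None, joints=None, frame_rate=30.0):
    positions = np.asarray(positions, dtype=float)
    n, j = positions.shape[:2]
    return SkeletonSequence(
        timestamps=np.arange(n) / frame_rate if timestamps is None else timestamps,
        joint_names=joints or tuple(f"J{i}" for i in range(j)),
        positions=positions,
        frame_rate=frame_rate,
    )


class TestSelectJoints:
    def test_20_joint_frame_reduces_to_6(self, subject, walk_bout, side_view):
        seq, _ = km.generate_sequence(subject, walk_bout, side_view, seed=0)
        out = select_joints(seq)
        assert out.joint_names == SELECTED_JOINTS
        assert out.positions.shape[1] == 6

    def test_idempotent(self, subject, walk_bout, side_view):
        seq, _ = km.generate_sequence(subject, walk_bout, side_view, seed=0)
        once = select_joints(seq)
        assert select_joints(once) is once

    def test_missing_joint_named_in_error(self):
        seq = _seq(np.zeros((3, 2, 3)), joints=("SHOULDER_LEFT", "ELBOW_LEFT"))
        with pytest.raises(KeyError, match="ANKLE_LEFT"):
            select_joints(seq)


class TestVelocities:
    def test_static_pose_gives_all_zero_matrix(self):
        fm = velocities(_seq(np.full((10, 6, 3), 1.0), joints=SELECTED_JOINTS))
        assert np.allclose(fm.values, 0.0)

    def test_hand_example_slope(self):
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = 0.1
        fm = velocities(_seq(pos, timestamps=np.array([0.0, 1.0 / 30.0])))
        assert fm.values[0, 0] == pytest.approx(3.0)

    def test_six_joints_three_axes_make_18_columns(self, subject, walk_bout, side_view):
        seq, _ = km.generate_sequence(subject, walk_bout, side_view, seed=0)
        fm = velocities(select_joints(seq))
        assert fm.n_features == 18
        assert fm.columns[0] == "SHOULDER_LEFT_vx"
        assert fm.columns[-1] == "ANKLE_LEFT_vz"

    def test_n_frames_give_n_minus_1_rows(self):
        fm = velocities(_seq(np.zeros((50, 2, 3))))
        assert len(fm) == 49

    def test_uniform_translation_gives_constant_velocity(self):
        t = np.arange(30) / 30.0
        pos = np.zeros((30, 2, 3))
        pos[:, :, 2] = (0.7 * t)[:, None]  # 0.7 m/s along z
        fm = velocities(_seq(pos))
        assert np.allclose(fm.values[:, 2], 0.7)
        assert np.allclose(fm.values[:, 5], 0.7)

    def test_duplicate_timestamps_rejected_at_construction(self):
        """The container already enforces strictly increasing timestamps,
        so a zero velocity denominator can never be reached."""
        with pytest.raises(ValueError, match="increasing"):
            _seq(np.zeros((3, 1, 3)), timestamps=np.array([0.0, 0.0, 0.1]))

    def test_view_rotation_carries_to_velocities(self, subject, walk_bout, noiseless_params):
        """Side-view velocities are the rear-view ones rotated by the yaw gap."""
        side, rear = km.CANONICAL_VIEWS[0], km.CANONICAL_VIEWS[2]
        world, _ = km.generate_bout(subject, walk_bout, noiseless_params, seed=3)
        v_side = velocities(select_joints(km.project_to_view(world, side))).values
        v_rear = velocities(select_joints(km.project_to_view(world, rear))).values
        # rear (yaw 0) -> side (yaw 90): vx' = vz, vz' = -vx, vy' = vy
        v3 = v_rear.reshape(-1, 6, 3)
        rotated = np.stack([v3[..., 2], v3[..., 1], -v3[..., 0]], axis=-1).reshape(v_rear.shape)
        assert np.allclose(v_side, rotated, atol=1e-12)


class TestPCA:
    def test_rank_one_data_needs_single_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=18)
        coeffs = rng.normal(size=200)
        X = np.outer(coeffs, direction)
        t = fit_pca(X)
        assert t.retained_count == 1

    def test_retention_rule_on_known_ratios(self):
        """Variance ratios [0.50, 0.30, 0.15, 0.05] need 3 components."""
        rng = np.random.default_rng(1)
        n = 200_00
        sds = np.sqrt(np.array([0.50, 0.30, 0.15, 0.05]))
        X = rng.standard_normal((n, 4)) * sds
        t = fit_pca(X, variance_threshold=0.90)
        assert t.retained_count == 3

    def test_isotropic_18d_needs_17_components(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20_000, 18))
        t = fit_pca(X, variance_threshold=0.90)
        assert t.retained_count == 17

    def test_components_orthonormal_and_ratios_sum_to_one(self, side_dataset):
        t = fit_pca(side_dataset.X[:2000])
        gram = t.loadings.T @ t.loadings
        assert np.allclose(gram, np.eye(t.retained_count), atol=1e-10)
        assert np.sum(t.explained_variance_ratio) == pytest.approx(1.0)

    def test_full_retention_reconstructs_exactly(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 5))
        t = fit_pca(X, variance_threshold=1.0)
        assert np.allclose(t.inverse_transform(t.transform(X)), X, atol=1e-10)

    def test_cumulative_variance_of_retained_meets_threshold(self, side_dataset):
        t = fit_pca(side_dataset.X[:3000], variance_threshold=0.90)
        assert np.cumsum(t.explained_variance_ratio)[t.retained_count - 1] >= 0.90

    def test_heldout_retained_variance_matches_train(self):
        rng = np.random.default_rng(4)
        sds = np.linspace(2.0, 0.1, 18)
        train = rng.standard_normal((4000, 18)) * sds
        test = rng.standard_normal((4000, 18)) * sds
        t = fit_pca(train)
        var_tr = t.transform(train).var(axis=0).sum()
        var_te = t.transform(test).var(axis=0).sum()
        assert var_te == pytest.approx(var_tr, rel=0.1)

    def test_dimension_mismatch_rejected(self):
        t = fit_pca(np.random.default_rng(5).standard_normal((50, 6)))
        with pytest.raises(ValueError, match="6"):
            t.transform(np.zeros((3, 4)))

    def test_zero_variance_input_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_pca(np.ones((10, 3)))

    def test_apply_pca_relabels_columns(self):
        fm = FeatureMatrix(
            values=np.random.default_rng(6).standard_normal((40, 4)),
            columns=("a", "b", "c", "d"),
        )
        out = apply_pca(fit_pca(fm, variance_threshold=0.5), fm)
        assert out.columns[0] == "PC1"
        assert out.n_features == fit_pca(fm, variance_threshold=0.5).retained_count

    def test_json_roundtrip(self, tmp_path):
        t = fit_pca(np.random.default_rng(7).standard_normal((60, 5)))
        p = tmp_path / "pca.json"
        t.to_json(p)
        t2 = km.PCATransform.from_json(p)
        assert np.allclose(t.loadings, t2.loadings)
        assert t.retained_count == t2.retained_count
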