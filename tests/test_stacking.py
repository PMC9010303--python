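import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucstack.errors import GeometryError, PairingError, StateError
from nucstack.frames import NucleosomeFrame
from nucstack.stacking import (
    StackStep,
    align_ensemble,
    ensemble_step_stats,
    nucleosome_frame,
    sampling_cloud,
    step_parameters,
    step_to_transform,
    superpose,
)
from nucstack.structio import TrajectoryEnsemble
from nucstack.synth import DispersionSpec, build_stack, sample_ensemble

from conftest import random_rigid_motion

IDENTITY_FRAME = NucleosomeFrame(np.zeros(3), np.array([1.0, 0, 0]),
                                 np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


def moved_frame(frame, R, t):
    return frame.transformed(R, t)


class TestSuperpose:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(30, 3)) * 10
        tf, rmsd = superpose(pts, pts)
        assert rmsd < 1e-9
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, 0, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_recovers_applied_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(20, 3)) * 15
        R, t = random_rigid_motion(rng)
        mobile = ref @ R.T + t          # mobile = R ref + t
        tf, rmsd = superpose(ref, mobile)
        assert rmsd < 1e-9
        np.testing.assert_allclose(tf.rotation, R.T, atol=1e-9)
        np.testing.assert_allclose(tf.apply(mobile), ref, atol=1e-8)

    def test_mirror_image_keeps_proper_rotation(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(25, 3)) * 10
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        tf, rmsd = superpose(ref, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.5

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_independent_implementation_on_noisy_sets(self, seed):
        """On noisy correspondences (RMSD > 0) the recovered rotation must
        match scipy's independent weighted-vector alignment."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(25, 3)) * 10
        R, t = random_rigid_motion(rng)
        mobile = ref @ R.T + t + rng.normal(scale=0.5, size=ref.shape)
        tf, rmsd = superpose(ref, mobile)
        est, _ = Rotation.align_vectors(ref - ref.mean(axis=0),
                                        mobile - mobile.mean(axis=0))
        np.testing.assert_allclose(tf.rotation, est.as_matrix(), atol=1e-8)
        assert rmsd > 0

    def test_size_mismatch_and_degenerate(self):
        with pytest.raises(PairingError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            superpose(line, line + 1.0)


class TestStepParameters:
    def test_identical_frames_give_zero_step(self):
        s = step_parameters(IDENTITY_FRAME, IDENTITY_FRAME)
        assert np.allclose(s.as_array(), [0, 0, 0, 0, 0, 0], atol=1e-9)

    def test_pure_translation_along_z_is_pure_rise(self):
        f2 = NucleosomeFrame(np.array([0, 0, 60.0]), IDENTITY_FRAME.x,
                             IDENTITY_FRAME.y, IDENTITY_FRAME.z)
        s = step_parameters(IDENTITY_FRAME, f2)
        assert s.rise == pytest.approx(60.0, abs=1e-9)
        assert abs(s.shift_x) < 1e-9 and abs(s.shift_y) < 1e-9
        assert s.tilt < 1e-9 and abs(s.twist) < 1e-9

    def test_pure_rotation_about_z_is_pure_twist(self):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("z", 20, degrees=True).as_matrix()
        f2 = moved_frame(IDENTITY_FRAME, R, np.zeros(3))
        s = step_parameters(IDENTITY_FRAME, f2)
        assert s.twist == pytest.approx(20.0, abs=1e-9)
        assert s.tilt < 1e-9 and abs(s.rise) < 1e-9

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariance_under_global_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        gt = StackStep(rng.uniform(40, 80), rng.uniform(-15, 15),
                       rng.uniform(-15, 15), rng.uniform(0, 40),
                       rng.uniform(-150, 150))
        tf = step_to_transform(IDENTITY_FRAME, gt)
        f2 = moved_frame(IDENTITY_FRAME, tf.rotation, tf.translation)
        R, t = random_rigid_motion(rng)
        s0 = step_parameters(IDENTITY_FRAME, f2)
        s1 = step_parameters(moved_frame(IDENTITY_FRAME, R, t),
                             moved_frame(f2, R, t))
        np.testing.assert_allclose(s1.as_array(), s0.as_array(), atol=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_swap_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        gt = StackStep(rng.uniform(40, 80), rng.uniform(-15, 15),
                       rng.uniform(-15, 15), rng.uniform(1, 40),
                       rng.uniform(-150, 150))
        tf = step_to_transform(IDENTITY_FRAME, gt)
        f2 = moved_frame(IDENTITY_FRAME, tf.rotation, tf.translation)
        fwd = step_parameters(IDENTITY_FRAME, f2)
        rev = step_parameters(f2, IDENTITY_FRAME)
        assert rev.twist == pytest.approx(-fwd.twist, abs=1e-8)
        assert rev.rise == pytest.approx(-fwd.rise, abs=1e-8)
        assert rev.tilt == pytest.approx(fwd.tilt, abs=1e-8)
        assert rev.center_distance == pytest.approx(fwd.center_distance, abs=1e-8)

    def test_center_distance_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s = StackStep(rng.uniform(-80, 80), rng.uniform(-30, 30),
                          rng.uniform(-30, 30), rng.uniform(0, 90),
                          rng.uniform(-179, 180))
            assert s.center_distance ** 2 == pytest.approx(
                s.rise ** 2 + s.shift_x ** 2 + s.shift_y ** 2, rel=1e-12)


class TestEnsembles:
    def test_rotated_copies_align_to_identical_frames(self, bare_stack):
        rng = np.random.default_rng(17)
        base = bare_stack.structure.coords[0]
        frames = []
        for _ in range(8):
            R, t = random_rigid_motion(rng)
            frames.append(base @ R.T + t)
        ens = TrajectoryEnsemble(bare_stack, np.array(frames))
        aligned = align_ensemble(ens, "N1")
        spread = aligned.frames.max(axis=0) - aligned.frames.min(axis=0)
        assert spread.max() < 1e-6
        assert aligned.aligned_on == "N1"

    def test_alignment_is_idempotent(self, bare_stack):
        coords = np.repeat(bare_stack.structure.coords, 4, axis=0)
        ens = TrajectoryEnsemble(bare_stack, coords)
        once = align_ensemble(ens, "N1")
        twice = align_ensemble(once, "N1")
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-9)

    def test_alignment_rmsd_matches_direct_superpose(self, bare_stack):
        ens = sample_ensemble(bare_stack, DispersionSpec(
            n_frames=5, seed=1, sigma_rise=2.0, sigma_tilt=5.0))
        rng = np.random.default_rng(2)
        shaken = []
        for i in range(ens.frame_count):
            R, t = random_rigid_motion(rng)
            shaken.append(ens.frames[i] @ R.T + t)
        shaken_ens = TrajectoryEnsemble(bare_stack, np.array(shaken))
        aligned = align_ensemble(shaken_ens, "N1")
        idx = bare_stack.structure.atom_indices(chain=["I", "J"], atom_name="C1'")
        ref = aligned.frames[0][idx]
        for i in range(1, aligned.frame_count):
            _, best = superpose(ref, shaken[i][idx])
            achieved = np.sqrt(np.mean(np.sum(
                (aligned.frames[i][idx] - ref) ** 2, axis=1)))
            assert achieved == pytest.approx(best, abs=1e-8)

    def test_sampling_cloud_requires_alignment(self, bare_stack):
        ens = TrajectoryEnsemble(bare_stack, bare_stack.structure.coords)
        with pytest.raises(StateError):
            sampling_cloud(ens, "N2")

    def test_constant_ensemble_has_zero_dispersion(self, bare_stack):
        coords = np.repeat(bare_stack.structure.coords, 6, axis=0)
        ens = TrajectoryEnsemble(bare_stack, coords, aligned_on="N1")
        pc = sampling_cloud(ens, "N2")
        assert pc.dyad_rms < 1e-9 and pc.anti_dyad_rms < 1e-9
        series, summary = ensemble_step_stats(ens, "N1", "N2")
        assert len(series) == 6
        assert (summary["sd"].to_numpy() < 1e-9).all()

    def test_summary_is_recomputable_from_series(self, bare_stack):
        ens = sample_ensemble(bare_stack, DispersionSpec(
            n_frames=40, seed=4, sigma_rise=1.0, sigma_twist=5.0))
        series, summary = ensemble_step_stats(ens, "N1", "N2")
        for p in ("rise", "twist", "tilt"):
            assert summary.loc[p, "mean"] == pytest.approx(series[p].mean())
            assert summary.loc[p, "sd"] == pytest.approx(series[p].std(ddof=1))
            assert summary.loc[p, "min"] == series[p].min()
            assert summary.loc[p, "max"] == series[p].max()


class TestGeneratorAnalyzerClosure:
    @pytest.mark.parametrize("gt", [
        StackStep(60.0, 0.0, 0.0, 0.0, 20.0),
        StackStep(55.0, 8.0, -5.0, 15.0, 45.0),
        StackStep(70.0, -12.0, 3.0, 30.0, -120.0),
    ])
    def test_built_stack_returns_ground_truth(self, gt):
        from nucstack.synth import StackSpec

        built = build_stack(StackSpec(step=gt, n_factors=0))
        rec = step_parameters(nucleosome_frame(built, "N1"),
                              nucleosome_frame(built, "N2"))
        np.testing.assert_allclose(rec.as_array(), gt.as_array(), atol=1e-6)
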