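"""Superposition, trajectory alignment, PCA and reconstruction."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gpcrdyn.essential import (align_trajectory, apply_transform,
                               kabsch_superpose, pca, reconstruct)
from gpcrdyn.metrics import rmsd_profile
from gpcrdyn.structures import Trajectory, select
from gpcrdyn.synthetic import (SyntheticSpec, default_planted_modes,
                               default_state_shift, make_trajectory)

from conftest import make_toy_structure


def brute_force_min_rmsd(mobile, target, seed=0):
    """Independent oracle: random rotation sampling refined by quasi-Newton
    minimization over the rotation vector."""
    mob = mobile - mobile.mean(axis=0)
    tgt = target - target.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((mob @ r.T - tgt) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = min((rng.uniform(-np.pi, np.pi, 3) for _ in range(300)), key=cost)
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return res.fun


class TestKabsch:
    def test_self_superposition_after_rigid_motion(self):
        s = make_toy_structure(8)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = s.coords @ rot.T + np.array([5.0, 5.0, 5.0])
        _, _, rmsd = kabsch_superpose(moved, s.coords)
        assert rmsd < 1e-10

    def test_matches_rotation_search_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(brute_force_min_rmsd(a, b), abs=1e-6)

    def test_no_improper_rotation_for_mirror_images(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(6, 3))
        mirrored = a * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = kabsch_superpose(mirrored, a)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        assert rmsd > 0.1

    def test_collinear_fit_set_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)


class TestAlignTrajectory:
    def test_jitter_only_alignment_recovers_reference(self, bundle):
        spec = SyntheticSpec(n_frames=5, noise_sd=0.0, rigid_jitter=(20.0, 4.0),
                             seed=2)
        traj, _ = make_trajectory(bundle, spec)
        aligned = align_trajectory(traj, 0, "ALL")
        for t in range(5):
            assert np.abs(aligned.frames[t] - aligned.frames[0]).max() < 1e-6

    def test_core_fit_leaves_loop_displacement_intact(self, bundle):
        """Loop RMSD measured after CORE alignment is unchanged if the
        already-aligned trajectory is aligned on CORE again."""
        shift = default_state_shift(bundle, norm=12.0)
        spec = SyntheticSpec(n_frames=10, noise_sd=0.05, transition_frame=5,
                             state_shift=shift, seed=4)
        traj, _ = make_trajectory(bundle, spec)
        prof1 = rmsd_profile(traj, 0, "CORE", "ICL3")
        realigned = align_trajectory(traj, 0, "CORE")
        prof2 = rmsd_profile(realigned, 0, "CORE", "ICL3")
        np.testing.assert_allclose(prof1.values, prof2.values, atol=1e-9)

    def test_single_frame_identity(self, bundle):
        traj = Trajectory(list(bundle.atoms), bundle.coords[None],
                          np.array([0.0]), dict(bundle.regions))
        aligned = align_trajectory(traj, 0, "ALL")
        np.testing.assert_allclose(aligned.frames, traj.frames, atol=1e-12)


class TestPCA:
    def test_single_mode_explains_everything(self, bundle):
        mode = default_planted_modes(bundle, 1)
        x0 = bundle.coords.ravel()
        frames = np.array([x0 + a * mode[0] for a in (-2.0, 2.0, -2.0, 2.0)])
        traj = Trajectory(list(bundle.atoms), frames.reshape(4, -1, 3),
                          0.2 * np.arange(4), dict(bundle.regions))
        result = pca(traj)
        assert result.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(np.dot(result.eigenvectors[:, 0], mode[0])) == pytest.approx(1.0, abs=1e-9)

    def test_two_planted_modes_variance_ratio(self, bundle):
        modes = default_planted_modes(bundle, 2)
        spec = SyntheticSpec(n_frames=5000, noise_sd=0.0, seed=6,
                             planted_modes=modes,
                             mode_variances=np.array([9.0, 1.0]))
        traj, _ = make_trajectory(bundle, spec)
        result = pca(traj)
        fr = result.variance_fractions
        assert fr[0] == pytest.approx(0.9, abs=0.02)
        assert fr[1] == pytest.approx(0.1, abs=0.02)

    def test_deterministic(self, bundle):
        spec = SyntheticSpec(n_frames=50, noise_sd=0.2, seed=8)
        traj, _ = make_trajectory(bundle, spec)
        r1 = pca(traj, n_modes=5)
        r2 = pca(traj, n_modes=5)
        np.testing.assert_array_equal(r1.eigenvectors, r2.eigenvectors)
        np.testing.assert_array_equal(r1.projections, r2.projections)

    def test_trace_identity(self, bundle):
        """Sum of all eigenvalues equals the total coordinate variance."""
        spec = SyntheticSpec(n_frames=80, noise_sd=0.4, seed=9)
        traj, _ = make_trajectory(bundle, spec)
        result = pca(traj)
        X = traj.frames.reshape(80, -1)
        total = np.sum(np.var(X, axis=0, ddof=1))
        assert result.total_variance == pytest.approx(total, rel=1e-6)

    def test_too_few_frames_rejected(self, bundle):
        traj = Trajectory(list(bundle.atoms), bundle.coords[None],
                          np.array([0.0]), dict(bundle.regions))
        with pytest.raises(ValueError, match="more than one frame"):
            pca(traj)


class TestReconstruct:
    def test_all_modes_reproduce_trajectory(self, bundle):
        spec = SyntheticSpec(n_frames=40, noise_sd=0.3, seed=10)
        traj, _ = make_trajectory(bundle, spec)
        result = pca(traj)
        rebuilt = reconstruct(result, np.arange(result.n_modes), traj)
        assert np.abs(rebuilt.frames - traj.frames).max() < 1e-6

    def test_single_mode_matches_noise_free_truth(self, bundle):
        mode = default_planted_modes(bundle, 1)
        spec = SyntheticSpec(n_frames=200, noise_sd=0.02, seed=11,
                             planted_modes=mode, mode_variances=np.array([9.0]))
        traj, truth = make_trajectory(bundle, spec)
        result = pca(traj)
        rebuilt = reconstruct(result, [0], traj)
        err = rebuilt.frames.reshape(200, -1) - truth.noise_free
        # mode-1 reconstruction differs from the planted truth only by the
        # noise floor (0.02 A per coordinate) and the finite-sample mean
        assert np.sqrt(np.mean(err**2)) < 0.05

    def test_empty_mode_set_rejected(self, bundle):
        spec = SyntheticSpec(n_frames=10, noise_sd=0.1, seed=12)
        traj, _ = make_trajectory(bundle, spec)
        result = pca(traj)
        with pytest.raises(ValueError, match="at least one mode"):
            reconstruct(result, [], traj)

    def test_out_of_range_mode_rejected(self, bundle):
        spec = SyntheticSpec(n_frames=10, noise_sd=0.1, seed=13)
        traj, _ = make_trajectory(bundle, spec)
        result = pca(traj, n_modes=3)
        with pytest.raises(IndexError):
            reconstruct(result, [7], traj)


class TestTransitionDetection:
    def test_mode1_projection_shows_planted_step(self, bundle):
        """Two-state trajectory: the leading PCA projection separates the
        states by more than 5x the within-state spread."""
        modes = default_planted_modes(bundle, 3)
        shift = default_state_shift(bundle, norm=25.0)
        shift -= modes.T @ (modes @ shift)
        shift *= 25.0 / np.linalg.norm(shift)
        spec = SyntheticSpec(n_frames=600, noise_sd=0.3, seed=14,
                             planted_modes=modes,
                             mode_variances=np.array([4.0, 2.0, 1.0]),
                             transition_frame=420, state_shift=shift,
                             rigid_jitter=(5.0, 2.0))
        traj, truth = make_trajectory(bundle, spec)
        aligned = align_trajectory(traj, 0, "ALL")
        result = pca(aligned)
        proj = result.projections[:, 0]
        pre, post = proj[truth.state_labels == 0], proj[truth.state_labels == 1]
        within_sd = max(pre.std(), post.std())
        assert abs(pre.mean() - post.mean()) > 5.0 * within_sd
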