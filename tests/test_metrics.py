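"""Per-frame observables: RMSD/RMSF profiles, distances, offsets, dihedrals."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrdyn.metrics import (com_offset_profile, dihedral_profile,
                             distance_profile, ionic_lock_profile,
                             rmsd_profile, rmsf)
from gpcrdyn.structures import AtomRecord, Structure, Trajectory
from gpcrdyn.synthetic import (SyntheticSpec, default_state_shift,
                               make_bundle, make_trajectory)

from conftest import make_static_trajectory, make_toy_structure


def rigid_move(frames, seed=0):
    """Apply an independent random rigid motion to every frame."""
    rng = np.random.default_rng(seed)
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        rot = Rotation.random(rng=rng).as_matrix()
        out[t] = frames[t] @ rot.T + rng.uniform(-20, 20, 3)
    return out


def dihedral_oracle(p0, p1, p2, p3):
    """Independent signed-dihedral formula via plane normals and the
    scalar triple product for the sign."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestRmsdProfile:
    def test_zero_at_reference_frame(self, bundle):
        spec = SyntheticSpec(n_frames=5, noise_sd=0.2, seed=1)
        traj, _ = make_trajectory(bundle, spec)
        prof = rmsd_profile(traj, 0, "CORE", "CORE")
        assert prof.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_jitter_only_profile_is_zero(self, bundle):
        spec = SyntheticSpec(n_frames=5, noise_sd=0.0, rigid_jitter=(25.0, 5.0),
                             seed=2)
        traj, _ = make_trajectory(bundle, spec)
        prof = rmsd_profile(traj, 0, "ALL", "ALL")
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-6)

    def test_two_state_step_matches_noise_free_oracle(self, bundle):
        shift = default_state_shift(bundle, norm=15.0)
        spec = SyntheticSpec(n_frames=10, noise_sd=0.0, transition_frame=5,
                             state_shift=shift)
        traj, truth = make_trajectory(bundle, spec)
        prof = rmsd_profile(traj, 0, "ALL", "ALL")
        # oracle: RMSD between the noise-free post/pre mean coordinates
        # after optimal superposition of the noise-free frames
        from gpcrdyn.essential import kabsch_superpose
        pre = truth.noise_free[0].reshape(-1, 3)
        post = truth.noise_free[-1].reshape(-1, 3)
        _, _, expected = kabsch_superpose(post, pre)
        np.testing.assert_allclose(prof.values[5:], expected, atol=1e-9)

    def test_structure_reference(self, bundle):
        spec = SyntheticSpec(n_frames=3, noise_sd=0.0)
        traj, _ = make_trajectory(bundle, spec)
        prof = rmsd_profile(traj, bundle, "ALL", "ALL")
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)


class TestRmsf:
    def test_static_trajectory_zero(self):
        s = make_toy_structure(6, regions={"FIT": frozenset({1, 2, 3})})
        traj = make_static_trajectory(s, 8)
        table = rmsf(traj, "FIT")
        np.testing.assert_allclose(table.values, 0.0, atol=1e-12)

    def test_localized_mode_rmsf_closed_form(self):
        """Mode on one atom with three equal components, variance sigma^2:
        that atom's RMSF equals sigma (Monte-Carlo tolerance)."""
        s = make_toy_structure(10, regions={"FIT": frozenset(range(1, 5))})
        n_frames, sigma = 4000, 1.5
        mode = np.zeros(30)
        mode[3 * 7: 3 * 7 + 3] = 1.0 / np.sqrt(3.0)
        rng = np.random.default_rng(3)
        amps = rng.normal(0.0, sigma, n_frames)
        frames = (s.coords.ravel()[None] + amps[:, None] * mode).reshape(n_frames, 10, 3)
        traj = Trajectory(list(s.atoms), frames, 0.2 * np.arange(n_frames),
                          dict(s.regions))
        table = rmsf(traj, "FIT")
        assert table.values[7] == pytest.approx(sigma, abs=3 * sigma / np.sqrt(2 * n_frames))
        np.testing.assert_allclose(np.delete(table.values, 7), 0.0, atol=1e-9)

    def test_post_transition_window_quieter_than_full(self, bundle):
        """Two-state loop trajectory: full-window loop RMSF is inflated by
        the mean shift; the post-transition window alone is quiet."""
        shift = default_state_shift(bundle, norm=30.0)
        spec = SyntheticSpec(n_frames=300, noise_sd=0.2, transition_frame=210,
                             state_shift=shift, seed=4)
        traj, _ = make_trajectory(bundle, spec)
        full = rmsf(traj, "CORE")
        late = rmsf(traj, "CORE", (210 * 0.2, 300 * 0.2))
        loop = (full.residue_indices >= 231) & (full.residue_indices <= 262)
        assert late.values[loop].mean() < 0.5 * full.values[loop].mean()

    def test_empty_window_rejected(self, bundle):
        spec = SyntheticSpec(n_frames=5, noise_sd=0.1, seed=5)
        traj, _ = make_trajectory(bundle, spec)
        with pytest.raises(ValueError, match="window"):
            rmsf(traj, "ALL", (100.0, 200.0))


class TestDistanceProfile:
    def test_known_geometry(self):
        atoms = [AtomRecord(1, "SER", "CA", "A", (0.0, 0.0, 0.0)),
                 AtomRecord(1, "SER", "OG", "A", (0.0, 0.0, 1.0)),
                 AtomRecord(2, "ASP", "CA", "A", (4.0, 0.0, 0.0)),
                 AtomRecord(2, "ASP", "CG", "A", (0.0, 0.0, 12.0))]
        s = Structure(atoms)
        traj = make_static_trajectory(s, 3)
        prof = distance_profile(traj, (1, "OG"), (2, "CG"))
        np.testing.assert_allclose(prof.values, 11.0, atol=1e-12)

    def test_invariant_under_rigid_motion(self, bundle):
        spec = SyntheticSpec(n_frames=10, noise_sd=0.3, seed=6)
        traj, _ = make_trajectory(bundle, spec)
        moved = traj.with_frames(rigid_move(traj.frames, seed=7))
        p1 = distance_profile(traj, (231, "CA"), (282, "CA"))
        p2 = distance_profile(moved, (231, "CA"), (282, "CA"))
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)

    def test_extrema_match_brute_force_scan(self, bundle):
        spec = SyntheticSpec(n_frames=50, noise_sd=0.5, seed=8)
        traj, _ = make_trajectory(bundle, spec)
        prof = distance_profile(traj, (113, "CA"), (207, "CA"))
        brute = [float(np.linalg.norm(traj.frames[t, 112] - traj.frames[t, 206]))
                 for t in range(50)]
        assert prof.values.min() == pytest.approx(min(brute), abs=1e-12)
        assert prof.values.max() == pytest.approx(max(brute), abs=1e-12)


class TestComOffset:
    def test_same_region_zero(self, bundle):
        traj, _ = make_trajectory(bundle, SyntheticSpec(n_frames=4, noise_sd=0.2, seed=9))
        prof = com_offset_profile(traj, "ICL3", "ICL3", "x")
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_single_atom_regions_exact(self):
        s = make_toy_structure(4, regions={"A": frozenset({1}), "B": frozenset({3})})
        traj = make_static_trajectory(s, 2)
        for axis, col in (("x", 0), ("y", 1), ("z", 2)):
            prof = com_offset_profile(traj, "A", "B", axis)
            expected = s.coords[0, col] - s.coords[2, col]
            np.testing.assert_allclose(prof.values, expected, atol=1e-12)

    def test_three_state_offsets_separate_by_kmeans(self, bundle):
        """Planted 3-state trajectory: x/y offset scatter forms three
        clouds recoverable with >= 95% purity."""
        from sklearn.cluster import KMeans
        dim = 3 * bundle.n_atoms
        s1 = default_state_shift(bundle, norm=40.0)
        rng = np.random.default_rng(10)
        perp = rng.normal(size=dim)
        loop_mask = np.zeros(dim, bool)
        idx = np.array([i for i, a in enumerate(bundle.atoms)
                        if 231 <= a.residue_index <= 262])
        loop_mask[(3 * idx[:, None] + np.arange(3)).ravel()] = True
        perp[~loop_mask] = 0.0
        perp -= s1 * np.dot(perp, s1) / np.dot(s1, s1)
        s2 = perp / np.linalg.norm(perp) * 40.0
        spec = SyntheticSpec(n_frames=300, noise_sd=0.3, seed=11,
                             transition_frame=[100, 200], state_shift=[s1, s2])
        traj, truth = make_trajectory(bundle, spec)
        x = com_offset_profile(traj, "CORE", "ICL3", "x").values
        y = com_offset_profile(traj, "CORE", "ICL3", "y").values
        points = np.column_stack([x, y])
        labels = KMeans(3, n_init=10, random_state=0).fit_predict(points)
        purity = sum(
            np.bincount(truth.state_labels[labels == c]).max()
            for c in range(3)
        ) / len(labels)
        assert purity >= 0.95

    def test_bad_axis_rejected(self, bundle):
        traj, _ = make_trajectory(bundle, SyntheticSpec(n_frames=3, noise_sd=0.0))
        with pytest.raises(ValueError, match="axis"):
            com_offset_profile(traj, "CORE", "ICL3", "w")


class TestIonicLock:
    @pytest.fixture()
    def lock_structure(self):
        return make_bundle(SyntheticSpec(), sidechain_map={
            131: ("ARG", ["CB", "CG", "CD", "NE", "NH1", "NH2"]),
            268: ("GLU", ["CB", "CG", "CD", "OE1", "OE2"]),
        })

    def test_min_over_pairs_matches_brute_force(self, lock_structure):
        spec = SyntheticSpec(n_frames=20, noise_sd=0.4, seed=12)
        traj, _ = make_trajectory(lock_structure, spec)
        lock, backbone = ionic_lock_profile(traj, 131, 268)
        from gpcrdyn.structures import atom_index
        donors = [atom_index(traj, 131, a) for a in ("NH1", "NH2", "NE")]
        acceptors = [atom_index(traj, 268, a) for a in ("OE1", "OE2")]
        for t in range(20):
            brute = min(np.linalg.norm(traj.frames[t, d] - traj.frames[t, a])
                        for d in donors for a in acceptors)
            assert lock.values[t] == pytest.approx(brute, abs=1e-12)
        ca = distance_profile(traj, (131, "CA"), (268, "CA"))
        np.testing.assert_allclose(backbone.values, ca.values, atol=1e-12)

    def test_missing_side_chain_rejected(self, bundle):
        traj, _ = make_trajectory(bundle, SyntheticSpec(n_frames=2, noise_sd=0.0))
        with pytest.raises(KeyError):
            ionic_lock_profile(traj, 131, 268)


class TestDihedral:
    def _traj_from_points(self, points):
        atoms = [AtomRecord(1, "GLU", name, "A", tuple(p))
                 for name, p in zip(("CB", "CG", "CD", "OE1"), points)]
        s = Structure(atoms)
        frames = np.asarray(points, dtype=float)[None]
        # dihedral needs no CA; bypass region machinery entirely
        return Trajectory(atoms, frames, np.array([0.0]))

    def test_cis_is_zero(self):
        traj = self._traj_from_points([(1, 1, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0)])
        prof = dihedral_profile(traj, 1, ("CB", "CG", "CD", "OE1"))
        assert prof.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        traj = self._traj_from_points([(1, 1, 0), (1, 0, 0), (2, 0, 0), (2, -1, 0)])
        prof = dihedral_profile(traj, 1, ("CB", "CG", "CD", "OE1"))
        assert abs(prof.values[0]) == pytest.approx(180.0, abs=1e-9)

    def test_random_geometry_matches_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 3.0
            traj = self._traj_from_points(pts)
            prof = dihedral_profile(traj, 1, ("CB", "CG", "CD", "OE1"))
            assert prof.values[0] == pytest.approx(
                dihedral_oracle(*pts), abs=1e-9)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(4, 3)) * 3.0
        traj = self._traj_from_points(pts)
        ref = dihedral_profile(traj, 1, ("CB", "CG", "CD", "OE1")).values[0]
        rot = Rotation.random(rng=rng).as_matrix()
        moved = self._traj_from_points(pts @ rot.T + np.array([3.0, -7.0, 2.0]))
        got = dihedral_profile(moved, 1, ("CB", "CG", "CD", "OE1")).values[0]
        assert got == pytest.approx(ref, abs=1e-9)
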