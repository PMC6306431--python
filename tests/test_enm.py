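"""Elastic-network, Kabsch, and mode-trajectory tests."""

import numpy as np
import pytest

from minorstate import enm
from minorstate.structures import StructureModel


def _struct(coords):
    n = len(coords)
    return StructureModel(
        chain=np.full(n, "A", dtype=object), resnum=np.arange(1, n + 1),
        resname=np.full(n, "GLY", dtype=object),
        atom_name=np.full(n, "CA", dtype=object),
        element=np.full(n, "C", dtype=object), coords=np.asarray(coords, float),
        source="test")


class TestNetwork:
    def test_spring_constant_formula(self):
        s = _struct([[0, 0, 0], [5, 0, 0], [0, 3, 0]])
        net = enm.build_network(s, cutoff=10.0, distance_weight=5.0)
        k = dict(zip(map(tuple, net.pairs), net.spring_constants))
        assert k[(0, 1)] == pytest.approx(np.exp(-1.0))

    def test_tirion_springs_uniform(self):
        s = _struct([[0, 0, 0], [5, 0, 0], [0, 3, 0]])
        net = enm.build_network(s, distance_weight=None)
        np.testing.assert_allclose(net.spring_constants, 1.0)

    def test_disconnected_network_rejected(self):
        s = _struct([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                     [30, 0, 0], [31, 0, 0], [30, 1, 0]])
        with pytest.raises(ValueError, match="disconnected"):
            enm.build_network(s, cutoff=10.0)

    def test_pair_list_matches_brute_force(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 15, size=(50, 3))
        net = enm.build_network(_struct(coords), cutoff=10.0)
        expected = {(i, j) for i in range(50) for j in range(i + 1, 50)
                    if np.linalg.norm(coords[i] - coords[j]) <= 10.0}
        assert set(map(tuple, net.pairs)) == expected


class TestModes:
    def test_equilateral_triangle_has_six_zero_modes(self):
        s = _struct([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0.01]])
        modes = enm.compute_modes(enm.build_network(s, cutoff=5.0))
        assert modes.n_zero_modes == 6
        assert np.sum(modes.eigenvalues > 1e-8) == 3

    def test_rigid_body_null_space(self, toy_structure):
        net = enm.build_network(toy_structure)
        H = enm.hessian(net)
        n = toy_structure.n_atoms
        for axis in range(3):
            t = np.zeros((n, 3))
            t[:, axis] = 1.0
            np.testing.assert_allclose(H @ t.ravel(), 0.0, atol=1e-10)
        # rotations about the centroid are also in the null space
        centered = toy_structure.coords - toy_structure.coords.mean(axis=0)
        for axis in np.eye(3):
            rot = np.cross(np.broadcast_to(axis, centered.shape), centered)
            np.testing.assert_allclose(H @ rot.ravel(), 0.0, atol=1e-8)

    def test_hessian_matches_finite_difference_energy(self, toy_structure):
        net = enm.build_network(toy_structure)
        H = enm.hessian(net)
        n3 = 3 * toy_structure.n_atoms
        x0 = toy_structure.coords.ravel().copy()
        h = 1e-5
        fd = np.zeros((n3, n3))
        for i in range(n3):
            for j in range(i, n3):
                def e(di, dj):
                    x = x0.copy()
                    x[i] += di
                    x[j] += dj
                    return enm.spring_energy(net, x.reshape(-1, 3))
                fd[i, j] = fd[j, i] = (
                    e(h, h) - e(h, -h) - e(-h, h) + e(-h, -h)) / (4 * h * h)
        np.testing.assert_allclose(H, fd, atol=1e-6 * np.abs(H).max())

    def test_eigenvalues_invariant_under_rotation(self, toy_structure):
        net1 = enm.build_network(toy_structure)
        m1 = enm.compute_modes(net1)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        rotated = toy_structure.with_coords(toy_structure.coords @ R.T)
        m2 = enm.compute_modes(enm.build_network(rotated))
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)

    def test_eigenvectors_orthonormal(self, toy_structure):
        modes = enm.compute_modes(enm.build_network(toy_structure))
        V = modes.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)

    def test_collinear_chain_rejected(self):
        s = _struct([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            enm.compute_modes(enm.build_network(s, cutoff=5.0))


class TestTrajectory:
    def test_zero_amplitude_frame_is_input(self, toy_structure):
        modes = enm.compute_modes(enm.build_network(toy_structure))
        traj = enm.mode_trajectory(toy_structure, modes, 7, n_frames=9, rescale=1.0)
        i0 = np.argmin(np.abs(traj.amplitudes))
        assert traj.amplitudes[i0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(traj.frames[i0].coords, toy_structure.coords)

    def test_rmsd_linear_in_amplitude(self, toy_structure):
        modes = enm.compute_modes(enm.build_network(toy_structure))
        traj = enm.mode_trajectory(toy_structure, modes, 7, n_frames=8)
        n = toy_structure.n_atoms
        for a, frame in zip(traj.amplitudes, traj.frames):
            rmsd = np.sqrt(np.mean(np.sum(
                (frame.coords - toy_structure.coords) ** 2, axis=1)))
            assert rmsd == pytest.approx(abs(a) / np.sqrt(n), rel=1e-9)

    @pytest.mark.parametrize("n_frames,rescale", [(8, 0.5), (17, 1.0)])
    def test_mean_rmsd_hits_rescale_target(self, toy_structure, n_frames, rescale):
        modes = enm.compute_modes(enm.build_network(toy_structure))
        traj = enm.mode_trajectory(toy_structure, modes, 7,
                                   n_frames=n_frames, rescale=rescale)
        rmsds = [np.sqrt(np.mean(np.sum((f.coords - toy_structure.coords) ** 2,
                                        axis=1))) for f in traj.frames]
        assert np.mean(rmsds) == pytest.approx(rescale, abs=1e-6)

    def test_rigid_body_mode_rejected(self, toy_structure):
        modes = enm.compute_modes(enm.build_network(toy_structure))
        with pytest.raises(ValueError, match="rigid"):
            enm.mode_trajectory(toy_structure, modes, 3)


class TestKabsch:
    def test_identical_structures_zero(self, toy_structure):
        rmsd, _, _ = enm.kabsch_rmsd(toy_structure, toy_structure)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_rotated_copy_zero(self, toy_structure):
        th = 1.1
        R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        other = toy_structure.with_coords(toy_structure.coords @ R.T + [3, -2, 5])
        rmsd, _, _ = enm.kabsch_rmsd(toy_structure, other)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, toy_structure):
        other = toy_structure.with_coords(
            toy_structure.coords + np.random.default_rng(1).normal(0, 0.3, (20, 3)))
        r_ab, _, _ = enm.kabsch_rmsd(toy_structure, other)
        r_ba, _, _ = enm.kabsch_rmsd(other, toy_structure)
        assert r_ab == pytest.approx(r_ba, rel=1e-9)

    def test_matches_rotation_grid_search_oracle(self):
        a = _struct([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]])
        rng = np.random.default_rng(2)
        b = _struct(a.coords + rng.normal(0, 0.4, size=(4, 3)))
        rmsd, _, _ = enm.kabsch_rmsd(a, b)
        # brute force over ZYZ Euler angles: coarse grid, then local refine
        pa = a.coords - a.coords.mean(axis=0)
        pb = b.coords - b.coords.mean(axis=0)

        def rz(t):
            return np.array([[np.cos(t), -np.sin(t), 0],
                             [np.sin(t), np.cos(t), 0], [0, 0, 1]])

        def ry(t):
            return np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0],
                             [-np.sin(t), 0, np.cos(t)]])

        def value(al, be, ga):
            R = rz(al) @ ry(be) @ rz(ga)
            return np.sqrt(np.mean(np.sum((pa @ R.T - pb) ** 2, axis=1)))

        def grid_best(centers, widths, n):
            best = (np.inf, None)
            for al in np.linspace(centers[0] - widths[0], centers[0] + widths[0], n):
                for be in np.linspace(centers[1] - widths[1], centers[1] + widths[1], n):
                    for ga in np.linspace(centers[2] - widths[2], centers[2] + widths[2], n):
                        v = value(al, be, ga)
                        if v < best[0]:
                            best = (v, (al, be, ga))
            return best

        best, center = grid_best((np.pi, np.pi / 2, np.pi),
                                 (np.pi, np.pi / 2, np.pi), 25)
        w = np.pi / 12
        for _ in range(4):
            best, center = grid_best(center, (w, w, w), 9)
            w /= 4
        assert rmsd == pytest.approx(best, abs=1e-3)

    def test_unmatched_atoms_reported(self, toy_structure):
        with pytest.raises(ValueError, match="unmatched"):
            enm.kabsch_rmsd(toy_structure,
                            toy_structure.subset(np.arange(2)))


class TestProfiles:
    def test_profile_against_start_is_linear(self, toy_structure):
        modes = enm.compute_modes(enm.build_network(toy_structure))
        traj = enm.mode_trajectory(toy_structure, modes, 7, n_frames=9)
        profile = enm.trajectory_rmsd_profile(traj, toy_structure)
        n = toy_structure.n_atoms
        for a, rmsd in profile:
            assert rmsd == pytest.approx(abs(a) / np.sqrt(n), abs=1e-8)

    def test_reference_at_interior_frame_minimizes_there(self, toy_structure):
        modes = enm.compute_modes(enm.build_network(toy_structure))
        traj = enm.mode_trajectory(toy_structure, modes, 7, n_frames=9)
        ref = traj.frames[6]
        profile = enm.trajectory_rmsd_profile(traj, ref)
        a_star, rmsd_min, interior = enm.find_min_amplitude(profile)
        assert interior
        assert a_star == pytest.approx(traj.amplitudes[6], abs=1e-6)
        assert rmsd_min < 1e-8

    def test_hinge_subset_profile_has_interior_minimum(self, hinge_set):
        open_s, closed_s, target_s, info, cfg = hinge_set
        modes = enm.compute_modes(enm.build_network(open_s))
        traj = enm.mode_trajectory(open_s, modes, 7, n_frames=33, rescale=1.5)
        moving_resnums = open_s.resnum[info["moving_mask"]].tolist()
        profile = enm.trajectory_rmsd_profile(
            traj, target_s, {"resnums": moving_resnums})
        a_star, rmsd_min, interior = enm.find_min_amplitude(profile)
        assert interior
        rmsds = [r for _, r in profile]
        assert rmsds[0] > rmsd_min and rmsds[-1] > rmsd_min

    def test_cumulative_low_mode_overlap_beats_random_directions(self, hinge_set):
        open_s, closed_s, _, info, _ = hinge_set
        _, rot, trans = enm.kabsch_rmsd(closed_s, open_s)
        disp = (closed_s.coords @ rot.T + trans) - open_s.coords
        modes = enm.compute_modes(enm.build_network(open_s))
        low = sum(enm.mode_overlap(modes, k, disp) for k in range(7, 13))
        rng = np.random.default_rng(0)
        n3 = 3 * open_s.n_atoms
        rand = np.linalg.qr(rng.normal(size=(n3, 6)))[0]
        d = disp.ravel() / np.linalg.norm(disp)
        rand_overlap = float(np.sum((rand.T @ d) ** 2))
        assert low > rand_overlap


class TestMinimumRefinement:
    def test_monotone_profile_minimum_at_end_not_interior(self):
        profile = [(a, 1.0 + 0.5 * a) for a in np.linspace(0, 5, 8)]
        a_star, _, interior = enm.find_min_amplitude(profile)
        assert not interior and a_star == 0.0

    def test_exact_parabola_vertex_recovered(self):
        a = np.linspace(-3, 5, 9)
        profile = list(zip(a, 2.0 + 0.3 * (a - 1.234) ** 2))
        a_star, rmsd_min, interior = enm.find_min_amplitude(profile)
        assert interior
        assert a_star == pytest.approx(1.234, abs=1e-9)
        assert rmsd_min == pytest.approx(2.0, abs=1e-9)
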