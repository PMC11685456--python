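"""Kabsch superposition, RMSD, and trajectory deviation series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hspdyn import (DegenerateGeometryError, DomainDefinition, RigidTransform,
                    Trajectory, domain_rmsd_series, kabsch_fit,
                    per_atom_deviation_series, rmsd, select_atom,
                    select_atoms)
from conftest import random_rotation


def brute_force_min_rmsd(mobile, reference, seed=0):
    """Independent minimum-RMSD search over rotations (no SVD).

    Coarse random quaternion sampling followed by shrinking local
    perturbation rounds, always comparing centroid-aligned point sets.
    """
    rng = np.random.default_rng(seed)
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)

    def score(R):
        return np.sqrt(np.mean(np.sum((x @ R.T - y) ** 2, axis=-1)))

    def quat_to_mat(q):
        w, a, b, c = q / np.linalg.norm(q)
        return np.array([
            [1 - 2 * (b * b + c * c), 2 * (a * b - w * c), 2 * (a * c + w * b)],
            [2 * (a * b + w * c), 1 - 2 * (a * a + c * c), 2 * (b * c - w * a)],
            [2 * (a * c - w * b), 2 * (b * c + w * a), 1 - 2 * (a * a + b * b)]])

    quats = rng.normal(size=(20000, 4))
    best_q, best = None, np.inf
    for q in quats:
        s = score(quat_to_mat(q))
        if s < best:
            best, best_q = s, q / np.linalg.norm(q)
    scale = 0.3
    for _ in range(8):
        for q in best_q + rng.normal(size=(3000, 4)) * scale:
            s = score(quat_to_mat(q))
            if s < best:
                best, best_q = s, q / np.linalg.norm(q)
        scale *= 0.35
    return best


class TestRmsd:
    def test_identical_sets_give_zero(self, rng):
        a = rng.normal(size=(7, 3))
        assert rmsd(a, a) == 0.0

    def test_hand_computed_value(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0]])
        b = np.array([[0.0, 0, 0], [1, 1, 0]])
        assert rmsd(a, b) == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        transform, r = kabsch_fit(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-10)

    def test_recovers_constructed_rotation_and_shift(self, rng):
        ref = rng.normal(size=(12, 3)) * 4
        theta = np.radians(30.0)
        Rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        mobile = ref @ Rz.T + np.array([1.0, 2.0, 3.0])
        transform, r = kabsch_fit(mobile, ref)
        assert r <= 1e-8
        np.testing.assert_allclose(transform.apply(mobile), ref, atol=1e-8)

    def test_matches_brute_force_rotation_search(self, rng):
        for trial in range(3):
            a = rng.normal(size=(10, 3)) * 3
            b = rng.normal(size=(10, 3)) * 3
            _, r_kabsch = kabsch_fit(a, b)
            r_brute = brute_force_min_rmsd(a, b, seed=trial)
            assert r_brute >= r_kabsch - 1e-9  # Kabsch is the true optimum
            assert r_brute - r_kabsch < 1e-3

    def test_reflection_branch_gives_proper_rotation(self, rng):
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[:, 0] = -b[:, 0]  # mirrored target tempts an improper fit
        transform, _ = kabsch_fit(a, b)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_inputs_raise(self, rng):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(line, rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            kabsch_fit(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fit_never_increases_rmsd_and_is_frame_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3)) * 2
        b = rng.normal(size=(8, 3)) * 2
        _, fitted = kabsch_fit(a, b)
        assert fitted <= rmsd(a, b) + 1e-12
        # simultaneous rigid transform of both inputs leaves the fit unchanged
        R = random_rotation(rng)
        t = rng.normal(size=3) * 5
        _, fitted2 = kabsch_fit(a @ R.T + t, b @ R.T + t)
        assert fitted2 == pytest.approx(fitted, abs=1e-8)


class TestTrajectorySeries:
    @pytest.fixture()
    def static_traj(self, helix30):
        coords = np.repeat(helix30.model(0)[None], 5, axis=0)
        return Trajectory(helix30, coords)

    def test_identical_frames_give_zero_series(self, static_traj, helix30):
        sel = select_atoms(helix30, DomainDefinition("d", "A", ((1, 30),)))
        series = domain_rmsd_series(static_traj, sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)
        assert series.mean == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_moved_frames_align_to_zero(self, helix30, rng):
        frames = [helix30.model(0)]
        for _ in range(4):
            R = random_rotation(rng)
            frames.append(helix30.model(0) @ R.T + rng.normal(size=3) * 10)
        traj = Trajectory(helix30, np.stack(frames))
        sel = select_atoms(helix30, DomainDefinition("d", "A", ((1, 30),)))
        series = domain_rmsd_series(traj, sel)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-6)

    def test_each_frame_equals_independent_kabsch(self, helix30, rng):
        coords = helix30.model(0) + rng.normal(0, 0.5, (6, helix30.n_atoms, 3))
        traj = Trajectory(helix30, coords)
        sel = select_atoms(helix30, DomainDefinition("d", "A", ((5, 25),)))
        series = domain_rmsd_series(traj, sel)
        for fi in range(6):
            _, expected = kabsch_fit(coords[fi, sel.indices],
                                     coords[0, sel.indices])
            assert series.values[fi] == pytest.approx(expected, abs=1e-12)

    def test_noise_series_mean_matches_analytic_expectation(self, helix30):
        # isotropic sigma=0 noise must give exactly zero
        coords = np.repeat(helix30.model(0)[None], 4, axis=0)
        sel = select_atoms(helix30, DomainDefinition("d", "A", ((1, 30),)))
        series = domain_rmsd_series(Trajectory(helix30, coords), sel)
        assert series.mean == pytest.approx(0.0, abs=1e-12)
        # large-count Gaussian noise: E[RMSD] ~ sigma*sqrt(3)*sqrt(2(n-?)..) --
        # superposition absorbs ~6 dof; for n atoms RMSD^2 ~ 2*3*sigma^2 per
        # pair minus fitted dof, dominated by sqrt(6)*sigma for n >> 1
        rng = np.random.default_rng(99)
        sigma = 0.2
        big = np.repeat(helix30.model(0)[None], 200, axis=0)
        big += rng.normal(0, sigma, big.shape)
        series = domain_rmsd_series(Trajectory(helix30, big), sel)
        expect = sigma * np.sqrt(6.0)  # both frames noisy: 2 * 3 sigma^2
        assert abs(series.values[1:].mean() - expect) / expect < 0.10

    def test_reference_frame_out_of_range(self, static_traj, helix30):
        sel = select_atoms(helix30, DomainDefinition("d", "A", ((1, 30),)))
        with pytest.raises(IndexError):
            domain_rmsd_series(static_traj, sel, reference_frame=99)


class TestPerAtomDeviation:
    def test_static_trajectory_is_all_zero(self, helix30):
        coords = np.repeat(helix30.model(0)[None], 3, axis=0)
        traj = Trajectory(helix30, coords)
        atoms = select_atom(helix30, "A", 15, "CA")
        align = select_atoms(helix30, DomainDefinition("a", "A", ((1, 10),)))
        series = per_atom_deviation_series(traj, atoms, align)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_single_displaced_atom_reports_its_shift(self, helix30):
        coords = np.repeat(helix30.model(0)[None], 3, axis=0)
        atoms = select_atom(helix30, "A", 25, "CA")
        coords[1, atoms.indices[0]] += np.array([0.0, 0.0, 2.0])
        traj = Trajectory(helix30, coords)
        align = select_atoms(helix30, DomainDefinition("a", "A", ((1, 10),)))
        series = per_atom_deviation_series(traj, atoms, align)
        np.testing.assert_allclose(series.values[[0, 2], 0], 0.0, atol=1e-9)
        assert series.values[1, 0] == pytest.approx(2.0, abs=1e-9)

    def test_matches_manual_per_frame_computation(self, helix30, rng):
        coords = helix30.model(0) + rng.normal(0, 0.4, (5, helix30.n_atoms, 3))
        traj = Trajectory(helix30, coords)
        atoms = select_atom(helix30, "A", 20, "CA")
        align = select_atoms(helix30, DomainDefinition("a", "A", ((1, 12),)))
        series = per_atom_deviation_series(traj, atoms, align)
        for fi in range(5):
            transform, _ = kabsch_fit(coords[fi, align.indices],
                                      coords[0, align.indices])
            moved = transform.apply(coords[fi, atoms.indices])
            expected = np.linalg.norm(moved - coords[0, atoms.indices], axis=1)
            np.testing.assert_allclose(series.values[fi], expected, atol=1e-12)


def test_rigid_transform_rejects_improper_matrix():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
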