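"""Superposition, RMSF, distance series, change points, PCA, mode coupling."""

import numpy as np
import pytest

from wraplab import structure_io as sio
from wraplab import synthetic as syn
from wraplab import trajectory as tj
from conftest import random_rotation


def rigid_motion_traj(structure, n_frames, rng):
    frames = []
    for _ in range(n_frames):
        R = random_rotation(rng)
        t = rng.normal(scale=5.0, size=3)
        frames.append(structure.coords @ R.T + t)
    return sio.Trajectory(structure, np.stack(frames),
                          np.arange(n_frames) * 0.01)


class TestSuperpose:
    def test_removes_rigid_motion(self, helix12, rng):
        s, _ = helix12
        traj = rigid_motion_traj(s, 10, rng)
        fitted = tj.superpose(traj, np.arange(s.n_atoms))
        mean = fitted.frames.mean(axis=0)
        rmsd = np.sqrt(((fitted.frames - mean) ** 2).sum(axis=2).mean(axis=1))
        assert rmsd.max() < 1e-6

    def test_idempotent_on_aligned_trajectory(self, dimer_traj):
        traj, _ = dimer_traj
        once = tj.superpose(traj, np.arange(traj.n_atoms))
        twice = tj.superpose(once, np.arange(traj.n_atoms))
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-6)

    def test_partial_fit_matches_single_frame_kabsch(self, dimer_traj):
        traj, _ = dimer_traj
        top = traj.topology
        selA = sio.select(top, "A", (1, 153), {"CA"})
        fitted = tj.superpose(traj, selA)
        mean = fitted.frames[:, selA].mean(axis=0)
        # each frame's chain-A RMSD must equal the optimal (Kabsch) RMSD
        for f in (0, len(fitted.frames) // 2):
            P = traj.frames[f][selA]
            R, t = tj._kabsch(P, mean)
            opt = np.sqrt(((P @ R.T + t - mean) ** 2).sum(axis=1).mean())
            got = np.sqrt(((fitted.frames[f][selA] - mean) ** 2).sum(axis=1).mean())
            assert got == pytest.approx(opt, abs=1e-8)

    def test_collinear_selection_errors(self, helix12):
        s, _ = helix12
        coords = np.zeros((s.n_atoms, 3))
        coords[:, 0] = np.arange(s.n_atoms)  # all atoms on a line
        line = s.with_coords(coords)
        traj = sio.Trajectory(line, np.stack([coords, coords + 1.0]), [0.0, 1.0])
        with pytest.raises(ValueError):
            tj.superpose(traj, np.arange(s.n_atoms))


class TestRMSF:
    def test_frozen_atoms_zero(self, helix12):
        s, _ = helix12
        frames = np.repeat(s.coords[None], 5, axis=0)
        traj = sio.Trajectory(s, frames, np.arange(5) * 0.1)
        prof = tj.rmsf(traj)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_isotropic_jitter_gives_sigma_sqrt3(self, helix12, rng):
        s, _ = helix12
        sigma = 0.4
        frames = s.coords[None] + rng.normal(scale=sigma,
                                             size=(10000, s.n_atoms, 3))
        traj = sio.Trajectory(s, frames, np.arange(10000) * 0.001)
        prof = tj.rmsf(traj)
        np.testing.assert_allclose(prof.rmsf, sigma * np.sqrt(3), rtol=0.05)

    def test_gnm_trajectory_matches_analytic(self, dimer_spec):
        traj, analytic = syn.sample_gnm_trajectory(dimer_spec, 5000)
        prof = tj.rmsf(traj)
        np.testing.assert_allclose(prof.rmsf, analytic, rtol=0.10)

    def test_short_window_errors(self, dimer_traj):
        traj, _ = dimer_traj
        with pytest.raises(ValueError):
            tj.rmsf(traj, window=(3, 4))

    def test_rigid_motion_invariance_post_fit(self, dimer_traj, rng):
        traj, _ = dimer_traj
        fitted = tj.superpose(traj, np.arange(traj.n_atoms))
        base = tj.rmsf(fitted).rmsf
        R = random_rotation(rng)
        moved = sio.Trajectory(traj.topology, fitted.frames @ R.T + 4.0,
                               fitted.times)
        refit = tj.superpose(moved, np.arange(traj.n_atoms))
        np.testing.assert_allclose(tj.rmsf(refit).rmsf, base, atol=1e-6)

    def test_restraint_contrast(self):
        """Pinning the electrostatic loop of chain A damps it while the
        partner chain's loop gains mobility — the restrained-vs-free
        comparison central to the dimer analysis."""
        spec0 = syn.sod1_like_dimer_spec(seed=21)
        lo, hi = spec0.el_range
        specR = syn.sod1_like_dimer_spec(
            seed=21, restrained=tuple(("A", r) for r in range(lo, hi + 1)))
        r0 = syn.gnm_analytic_rmsf(spec0)
        r1 = syn.gnm_analytic_rmsf(specR)
        top = syn._dimer_topology(spec0)
        elA = [top.residue_index("A", r, "") for r in range(lo, hi + 1)]
        elF = [top.residue_index("F", r, "") for r in range(lo, hi + 1)]
        assert r1[elA].mean() < r0[elA].mean() / 5
        assert np.all(r1[elF] > r0[elF])


class TestDistanceSeries:
    def test_static_structure_constant(self, helix12):
        s, _ = helix12
        frames = np.repeat(s.coords[None], 6, axis=0)
        traj = sio.Trajectory(s, frames, np.arange(6) * 0.1)
        series = tj.distance_series(traj, ("A", 2), ("A", 9), mode="ca")
        assert np.ptp(series.values) == 0.0

    def test_linear_motion_linear_series(self, helix12):
        s, _ = helix12
        frames = np.repeat(s.coords[None], 20, axis=0)
        idx = s.atoms_of_residue(11)
        for f in range(20):
            frames[f][idx] += np.array([0.0, 0.0, f * 1.0])
        traj = sio.Trajectory(s, frames, np.arange(20) * 0.1)
        series = tj.distance_series(traj, ("A", 1), ("A", 12), mode="ca")
        diffs = np.diff(series.values)
        assert np.allclose(diffs, diffs[-1], atol=0.2) or np.all(diffs >= -1e-9)

    def test_min_mode_bounded_by_ca_mode(self, dimer_traj):
        traj, _ = dimer_traj
        a, b = ("A", 50), ("F", 130)
        s_min = tj.distance_series(traj, a, b, mode="min")
        s_ca = tj.distance_series(traj, a, b, mode="ca")
        assert np.all(s_min.values <= s_ca.values + 1e-9)

    def test_missing_residue_errors(self, dimer_traj):
        traj, _ = dimer_traj
        with pytest.raises(sio.SelectionError):
            tj.distance_series(traj, ("A", 9999), ("F", 130))


class TestTransitions:
    @staticmethod
    def series(values, dt=0.002):
        return tj.DistanceSeries(("x", "y"), "ca", np.asarray(values, float),
                                 np.arange(len(values)) * dt)

    def test_flat_series_no_change_points(self):
        assert tj.detect_transitions(self.series(np.full(500, 8.0)),
                                     min_shift=1.0, min_dwell=50) == []

    def test_planted_step_recovered(self, rng):
        v = 8.0 + 0.2 * rng.standard_normal(1000)
        v[600:] += 4.0
        cps = tj.detect_transitions(self.series(v), min_shift=2.0, min_dwell=50)
        assert len(cps) == 1
        assert abs(cps[0].frame - 600) <= 50
        assert cps[0].after_mean - cps[0].before_mean == pytest.approx(4.0, abs=0.3)

    def test_contraction_then_expansion_recovered_in_order(self, rng):
        """Mimics the ~1.2 ns contraction followed by the ~1.4 ns expansion."""
        v = 8.0 + 0.2 * rng.standard_normal(1000)
        v[600:] -= 4.0   # contraction
        v[800:] += 6.0   # expansion
        cps = tj.detect_transitions(self.series(v), min_shift=2.0, min_dwell=50)
        assert len(cps) == 2
        assert abs(cps[0].frame - 600) <= 50 and abs(cps[1].frame - 800) <= 50
        assert cps[0].after_mean < cps[0].before_mean
        assert cps[1].after_mean > cps[1].before_mean

    def test_no_false_positives_on_iid_noise(self):
        sigma = 0.3
        for seed in range(30):
            r = np.random.default_rng(seed)
            v = 8.0 + sigma * r.standard_normal(600)
            assert tj.detect_transitions(self.series(v), min_shift=5 * sigma,
                                         min_dwell=50) == []


class TestPCA:
    def test_modes_orthonormal_and_sorted(self, dimer_traj):
        traj, _ = dimer_traj
        fitted = tj.superpose(traj, np.arange(traj.n_atoms))
        modes = tj.pca_modes(fitted, n_modes=6)
        evals = [m.eigenvalue for m in modes]
        assert evals == sorted(evals, reverse=True)
        M = np.stack([m.eigenvector.ravel() for m in modes])
        np.testing.assert_allclose(M @ M.T, np.eye(6), atol=1e-8)

    def test_eigenvalue_sum_equals_total_variance(self, dimer_traj):
        traj, _ = dimer_traj
        fitted = tj.superpose(traj, np.arange(traj.n_atoms))
        modes = tj.pca_modes(fitted, n_modes=3 * traj.n_atoms)
        X = fitted.frames.reshape(fitted.n_frames, -1)
        Xc = X - X.mean(axis=0)
        total = (Xc ** 2).sum() / fitted.n_frames
        assert sum(m.eigenvalue for m in modes) == pytest.approx(total, rel=1e-8)

    def test_planted_mode_recovered(self, dimer_spec):
        quiet = syn.sod1_like_dimer_spec(seed=5, temperature_scale=0.05)
        base, _ = syn.sample_gnm_trajectory(quiet, 600)
        top = base.topology
        lo, hi = quiet.el_range
        elA = sio.select(top, "A", (lo, hi), {"CA"})
        elF = sio.select(top, "F", (lo, hi), {"CA"})
        shape = syn.breathing_mode_shape(top, elA, elF)
        amps = 3.0 * np.sin(np.linspace(0, 12 * np.pi, 600))
        planted = syn.plant_collective_mode(base, shape, amps)
        fitted = tj.superpose(planted, np.arange(top.n_atoms))
        m0 = tj.pca_modes(fitted, n_modes=1)[0]
        cos = abs(np.dot(m0.eigenvector.ravel(), shape.ravel()))
        assert cos >= 0.9
        assert abs(tj.mode_coupling(m0, elA, elF)) >= 0.9

    def test_too_few_frames_errors(self, helix12):
        s, _ = helix12
        traj = sio.Trajectory(s, np.repeat(s.coords[None], 2, axis=0), [0, 1])
        with pytest.raises(ValueError):
            tj.pca_modes(traj)


class TestModeCoupling:
    def test_independent_loops_low_coupling(self, dimer_spec):
        # only chain A's loop moves in the planted mode -> no correlated
        # displacement to report; a mode with motion in one loop only
        quiet = syn.sod1_like_dimer_spec(seed=6, temperature_scale=0.02)
        base, _ = syn.sample_gnm_trajectory(quiet, 500)
        top = base.topology
        lo, hi = quiet.el_range
        elA = sio.select(top, "A", (lo, hi), {"CA"})
        zlF = sio.select(top, "F", quiet.zl_range, {"CA"})
        shape = np.zeros((top.n_atoms, 3))
        shape[elA, 1] = 1.0
        shape /= np.linalg.norm(shape)
        rngl = np.random.default_rng(3)
        amps = 2.0 * rngl.standard_normal(500)
        planted = syn.plant_collective_mode(base, shape, amps)
        fitted = tj.superpose(planted, np.arange(top.n_atoms))
        m0 = tj.pca_modes(fitted, n_modes=1)[0]
        va = m0.eigenvector[[list(m0.atom_indices).index(a) for a in elA]]
        assert np.linalg.norm(va.mean(axis=0)) > 0.01  # loop A dominates
        # partner region barely participates; coupling is not meaningful
        # but must stay bounded when defined
        try:
            c = tj.mode_coupling(m0, elA, zlF)
            assert -1.0 <= c <= 1.0
        except ValueError:
            pass  # zero displacement in the quiet region is acceptable

    def test_identical_selections_forbidden(self, dimer_traj):
        traj, _ = dimer_traj
        fitted = tj.superpose(traj, np.arange(traj.n_atoms))
        m0 = tj.pca_modes(fitted, n_modes=1)[0]
        sel = np.arange(5)
        with pytest.raises(ValueError):
            tj.mode_coupling(m0, sel, sel)
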