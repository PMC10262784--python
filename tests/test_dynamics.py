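import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trajkit._geom import rotation_about_axis
from trajkit.dynamics import (
    CovarianceMatrix,
    align_trajectory,
    correlated_partners,
    covariance_matrix,
    kabsch_superpose,
    rmsd_series,
    rmsf_profile,
)
from trajkit.errors import TrajkitError
from trajkit.model_io import Trajectory, resolve_selection
from trajkit.synthetic import build_ideal_helix


def grid_search_min_rmsd(mobile, reference):
    """Independent oracle: minimize RMSD over rotations by coarse grid +
    simplex refinement of a rotation-vector parameterization."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mob = mobile - mobile.mean(0)
    ref = reference - reference.mean(0)

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((mob @ r.T - ref) ** 2).sum(1).mean())

    best = None
    for ax in np.eye(3):
        for angle in np.arange(0.0, 2 * np.pi, np.pi / 6):
            res = minimize(rmsd_of, ax * angle, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            if best is None or res.fun < best:
                best = res.fun
    return best


class TestKabsch:
    def test_self_superposition_is_identity(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        res = kabsch_superpose(x, x)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(res.translation, 0.0, atol=1e-10)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_constructed_rotation_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 3))
        r0 = rotation_about_axis([0.0, 0.0, 1.0], 30.0)
        t0 = np.array([1.0, -2.0, 0.5])
        y = x @ r0.T + t0
        res = kabsch_superpose(x, y)
        assert np.abs(res.rotation - r0).max() < 1e-8
        assert res.rmsd < 1e-8

    def test_matches_grid_search_oracle(self):
        x = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        y = x.copy()
        y[0, 0] += 1.0  # one atom displaced 1 A
        res = kabsch_superpose(x, y)
        oracle = grid_search_min_rmsd(x, y)
        assert res.rmsd == pytest.approx(oracle, abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(TrajkitError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(TrajkitError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_rotation_always_proper_orthonormal(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 3))
        y = rng.normal(size=(8, 3))
        res = kabsch_superpose(x, y)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_weighted_fit_prefers_heavy_atoms(self):
        x = np.array([[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]])
        y = x.copy()
        y[3] += (2.0, 0, 0)
        w = np.array([1.0, 1.0, 1.0, 1e-9])
        res = kabsch_superpose(x, y, weights=w)
        # the three heavily weighted atoms superpose essentially exactly
        assert res.rmsd < 1e-4


class TestAlignment:
    def test_rigid_motion_fully_removed(self, helix12):
        rng = np.random.default_rng(5)
        frames = []
        for _ in range(10):
            axis = rng.standard_normal(3)
            rot = rotation_about_axis(axis, rng.uniform(0, 360))
            frames.append(helix12.coords @ rot.T + rng.uniform(-10, 10, 3))
        traj = Trajectory(helix12, np.array(frames), 250.0)
        fit = resolve_selection(helix12, "backbone")
        aligned = align_trajectory(traj, fit)
        dev = np.sqrt(((aligned.frames - aligned.frames[0]) ** 2).sum(2).mean(1))
        assert np.all(dev < 1e-6)

    def test_alignment_idempotent(self, helix10_traj):
        fit = resolve_selection(helix10_traj.topology, "backbone")
        once = align_trajectory(helix10_traj, fit)
        twice = align_trajectory(once, fit)
        assert np.allclose(once.frames, twice.frames, atol=1e-9)

    def test_ref_frame_out_of_range(self, helix10_traj):
        fit = resolve_selection(helix10_traj.topology, "backbone")
        with pytest.raises(TrajkitError):
            align_trajectory(helix10_traj, fit, ref_frame=999)


class TestRMSD:
    def test_static_trajectory_is_zero(self, helix12):
        traj = Trajectory(helix12, np.repeat(helix12.coords[None], 4, axis=0), 250.0)
        sel = resolve_selection(helix12, "all")
        assert np.allclose(rmsd_series(traj, sel, refit=False), 0.0)

    def test_pure_translation(self, helix12):
        frames = np.stack([helix12.coords, helix12.coords + (3.0, 4.0, 0.0)])
        traj = Trajectory(helix12, frames, 250.0)
        sel = resolve_selection(helix12, "all")
        no_refit = rmsd_series(traj, sel, refit=False)
        refit = rmsd_series(traj, sel, refit=True)
        assert no_refit[1] == pytest.approx(5.0, abs=1e-12)
        assert refit[1] == pytest.approx(0.0, abs=1e-9)

    def test_refit_never_exceeds_unrefit(self, helix10_traj):
        sel = resolve_selection(helix10_traj.topology, "name CA")
        refit = rmsd_series(helix10_traj, sel, refit=True)
        raw = rmsd_series(helix10_traj, sel, refit=False)
        assert np.all(refit <= raw + 1e-9)


class TestRMSF:
    def test_static_is_zero(self, helix12):
        traj = Trajectory(helix12, np.repeat(helix12.coords[None], 3, axis=0), 250.0)
        sel = resolve_selection(helix12, "name CA")
        assert np.allclose(rmsf_profile(traj, sel).values, 0.0)

    def test_two_point_alternation(self, helix12):
        a = 0.7
        f0 = helix12.coords.copy()
        f1 = helix12.coords.copy()
        f0[0, 0] -= a
        f1[0, 0] += a
        traj = Trajectory(helix12, np.array([f0, f1] * 10), 250.0)
        sel = resolve_selection(helix12, "name N and resid 1")
        prof = rmsf_profile(traj, sel, group_by_residue=False)
        assert prof.values[0] == pytest.approx(a, abs=1e-12)

    def test_needs_two_frames(self, helix12):
        traj = Trajectory(helix12, helix12.coords[None], 250.0)
        sel = resolve_selection(helix12, "name CA")
        with pytest.raises(TrajkitError):
            rmsf_profile(traj, sel)


class TestCovariance:
    def _traj_with_displacements(self, base, disp_per_res):
        """Frames where each residue moves rigidly by the given per-frame
        3-vectors (dict resid -> (T, 3))."""
        t = len(next(iter(disp_per_res.values())))
        frames = np.repeat(base.coords[None], t, axis=0)
        for i, atom in enumerate(base.atoms):
            d = disp_per_res.get(atom.residue_index)
            if d is not None:
                frames[:, i, :] += d
        return Trajectory(base, frames, 250.0)

    def test_identical_displacements_correlate_plus_one(self, helix12, ca_selection):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(50, 3))
        traj = self._traj_with_displacements(helix12, {3: d, 9: d.copy()})
        cov = covariance_matrix(traj, ca_selection(traj))
        assert cov.entry(("A", 3), ("A", 9)) == pytest.approx(1.0, abs=1e-6)

    def test_opposite_displacements_correlate_minus_one(self, helix12, ca_selection):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(50, 3))
        traj = self._traj_with_displacements(helix12, {3: d, 9: -d})
        cov = covariance_matrix(traj, ca_selection(traj))
        assert cov.entry(("A", 3), ("A", 9)) == pytest.approx(-1.0, abs=1e-6)

    def test_independent_residues_near_zero(self, ca_selection):
        from trajkit.synthetic import FluctuationSpec, simulate_trajectory

        base = build_ideal_helix(6)
        traj = simulate_trajectory(
            base, FluctuationSpec(per_residue_amplitude=0.5, seed=8), 5000
        )
        cov = covariance_matrix(traj, ca_selection(traj))
        off = cov.values[~np.eye(len(cov.labels), dtype=bool)]
        assert np.abs(off).max() <= 0.1

    def test_zero_variance_residue_zeroed_with_warning(self, helix12, ca_selection):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(40, 3))
        traj = self._traj_with_displacements(helix12, {3: d})  # others static
        with pytest.warns(UserWarning, match="zero variance"):
            cov = covariance_matrix(traj, ca_selection(traj))
        i3 = cov.labels.index(("A", 3))
        row = cov.values[i3].copy()
        row[i3] = 0.0
        assert np.allclose(row, 0.0)
        assert np.allclose(np.diag(cov.values), 1.0)

    def test_matrix_invariants(self, helix10_traj, ca_selection):
        cov = covariance_matrix(helix10_traj, ca_selection(helix10_traj))
        v = cov.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0, atol=1e-10)
        assert np.all(np.abs(v) <= 1.0 + 1e-10)


class TestCorrelatedPartners:
    def _cov(self, n, entries):
        v = np.eye(n)
        for (i, j), c in entries.items():
            v[i, j] = v[j, i] = c
        labels = [("A", k + 1) for k in range(n)]
        return CovarianceMatrix(labels=labels, values=v)

    def test_threshold_crossings(self):
        cov = self._cov(5, {(0, 2): 0.8, (0, 4): -0.76, (0, 1): 0.5})
        partners = correlated_partners(cov, ("A", 1), threshold=0.75)
        assert partners == [(("A", 3), pytest.approx(0.8)),
                            (("A", 5), pytest.approx(-0.76))]

    def test_no_partners_when_uncorrelated(self):
        cov = self._cov(4, {})
        assert correlated_partners(cov, ("A", 2)) == []

    def test_unknown_residue_rejected(self):
        cov = self._cov(3, {})
        with pytest.raises(TrajkitError):
            correlated_partners(cov, ("B", 99))
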