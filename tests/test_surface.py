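import numpy as np
import pytest

from trajkit._geom import rotation_about_axis
from trajkit.errors import TrajkitError
from trajkit.model_io import (
    AtomRecord,
    Structure,
    Trajectory,
    assign_masses_radii,
    resolve_selection,
    selection_from_indices,
)
from trajkit.surface import buried_surface_area, sasa_series, shrake_rupley_sasa
from trajkit.synthetic import build_ideal_helix
from trajkit._geom import fibonacci_sphere


def carbon_cluster(positions, chain="A"):
    """Structure of bare carbon atoms at the given coordinates."""
    atoms = [
        AtomRecord(serial=i + 1, atom_name="C", element="C", residue_name="UNK",
                   residue_index=i + 1, chain_id=chain)
        for i in range(len(positions))
    ]
    return assign_masses_radii(Structure(atoms, np.asarray(positions, float)))


def mc_sphere_sasa(centers, radii, probe, n_samples, seed=0):
    """Monte-Carlo surface-sampling oracle: random points on each solvent
    sphere, kept when outside every other solvent sphere."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, float)
    solv = np.asarray(radii, float) + probe
    total = 0.0
    for i in range(len(centers)):
        pts = rng.standard_normal((n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = centers[i] + solv[i] * pts
        exposed = np.ones(n_samples, dtype=bool)
        for j in range(len(centers)):
            if j == i:
                continue
            exposed &= np.linalg.norm(pts - centers[j], axis=1) >= solv[j]
        total += exposed.mean() * 4.0 * np.pi * solv[i] ** 2
    return total


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        s = carbon_cluster([[0.0, 0.0, 0.0]])
        res = shrake_rupley_sasa(s, probe=1.4, n_points=960)
        exact = 4.0 * np.pi * 3.10**2
        assert res.total == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_additive(self):
        s = carbon_cluster([[0.0, 0, 0], [100.0, 0, 0]])
        res = shrake_rupley_sasa(s)
        single = 4.0 * np.pi * 3.10**2
        assert res.total == pytest.approx(2 * single, rel=0.01)

    def test_overlapping_pair_matches_mc_oracle(self):
        s = carbon_cluster([[0.0, 0, 0], [2.0, 0, 0]])
        res = shrake_rupley_sasa(s, n_points=960)
        oracle = mc_sphere_sasa(s.coords, [1.70, 1.70], 1.4, 300_000, seed=1)
        assert res.total == pytest.approx(oracle, rel=0.02)

    def test_per_residue_sums_equal_per_atom(self, helix12):
        res = shrake_rupley_sasa(helix12, n_points=240)
        assert sum(res.per_residue.values()) == pytest.approx(
            res.per_atom.sum(), abs=1e-6
        )

    def test_quadrature_convergence(self, helix12):
        a = shrake_rupley_sasa(helix12, n_points=960).total
        b = shrake_rupley_sasa(helix12, n_points=1920).total
        assert abs(b - a) / a <= 0.005

    def test_rigid_motion_invariance(self, helix12):
        rot = rotation_about_axis([1.0, 2.0, 3.0], 73.0)
        moved = helix12.with_coords(helix12.coords @ rot.T + (5.0, -3.0, 8.0))
        a = shrake_rupley_sasa(helix12, n_points=960).total
        b = shrake_rupley_sasa(moved, n_points=960).total
        assert abs(b - a) / a <= 0.005

    def test_approaching_neighbor_monotonically_buries(self):
        areas = []
        for d in (8.0, 6.0, 5.0, 4.0, 3.0, 2.0):
            s = carbon_cluster([[0.0, 0, 0], [d, 0, 0]])
            sel = selection_from_indices([0])
            areas.append(shrake_rupley_sasa(s, subset=sel).total)
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(areas, areas[1:]))

    def test_missing_radii_rejected(self):
        atoms = [AtomRecord(1, "C", "C", "UNK", 1, "A")]
        s = Structure(atoms, np.zeros((1, 3)))
        with pytest.raises(TrajkitError):
            shrake_rupley_sasa(s)


class TestSASASeries:
    def test_caged_atom_has_no_surface(self):
        shell = 3.0 * fibonacci_sphere(40)
        s = carbon_cluster(np.vstack([[[0.0, 0, 0]], shell]))
        traj = Trajectory(s, s.coords[None], 250.0)
        target = selection_from_indices([0])
        series = sasa_series(traj, target, n_points=960)
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_static_trajectory_constant(self, helix12):
        traj = Trajectory(helix12, np.repeat(helix12.coords[None], 3, axis=0), 250.0)
        sel = resolve_selection(helix12, "resid 6")
        series = sasa_series(traj, sel, n_points=240)
        assert np.allclose(series, series[0])

    def test_two_state_series_matches_per_state_values(self):
        from trajkit.synthetic import TwoStateSpec, simulate_two_state, build_peptide
        from trajkit.synthetic import ALPHA_HELIX, BETA_STRAND

        a = build_peptide([ALPHA_HELIX] * 8)
        b = build_peptide([ALPHA_HELIX] * 4 + [BETA_STRAND] * 4)
        traj = simulate_two_state(TwoStateSpec(a, b, 0.5, seed=2), 20, jitter=0.0)
        sel = resolve_selection(a, "resid 6")
        series = sasa_series(traj, sel, n_points=240)
        sasa_a = shrake_rupley_sasa(a, subset=sel, n_points=240).total
        sasa_b = shrake_rupley_sasa(b, subset=sel, n_points=240).total
        labels = np.array(traj.metadata["planted"]["labels"])
        assert np.allclose(series[labels == 0], sasa_a, atol=1e-9)
        assert np.allclose(series[labels == 1], sasa_b, atol=1e-9)

    def test_target_outside_context_rejected(self, helix12):
        traj = Trajectory(helix12, helix12.coords[None], 250.0)
        target = resolve_selection(helix12, "resid 6")
        context = resolve_selection(helix12, "resid 1-3")
        with pytest.raises(TrajkitError):
            sasa_series(traj, target, context)


class TestBuriedSurfaceArea:
    def test_distant_chains_zero(self):
        s = carbon_cluster([[0.0, 0, 0], [100.0, 0, 0]])
        traj = Trajectory(s, s.coords[None], 250.0)
        a = selection_from_indices([0])
        b = selection_from_indices([1])
        bsa = buried_surface_area(traj, a, b)
        assert bsa.values[0] == pytest.approx(0.0, abs=1e-6)

    def test_two_sphere_overlap_matches_mc_oracle(self):
        s = carbon_cluster([[0.0, 0, 0], [3.0, 0, 0]])
        traj = Trajectory(s, s.coords[None], 250.0)
        a = selection_from_indices([0])
        b = selection_from_indices([1])
        bsa = buried_surface_area(traj, a, b, n_points=960).values[0]
        mc_ab = mc_sphere_sasa(s.coords, [1.70, 1.70], 1.4, 300_000, seed=2)
        single = 4.0 * np.pi * 3.10**2
        oracle = (2 * single - mc_ab) / 2.0
        assert bsa == pytest.approx(oracle, rel=0.02)

    def test_symmetric_and_deterministic(self, helix12):
        traj = Trajectory(helix12, np.repeat(helix12.coords[None], 2, axis=0), 250.0)
        a = resolve_selection(helix12, "resid 1-6")
        b = resolve_selection(helix12, "resid 7-12")
        ab = buried_surface_area(traj, a, b, n_points=240).values
        ba = buried_surface_area(traj, b, a, n_points=240).values
        assert np.allclose(ab, ba, atol=1e-9)  # summation order differs
        assert ab[0] == ab[1]
        assert np.all(ab >= 0.0)

    def test_overlapping_selections_rejected(self, helix12):
        traj = Trajectory(helix12, helix12.coords[None], 250.0)
        a = resolve_selection(helix12, "resid 1-6")
        b = resolve_selection(helix12, "resid 6-12")
        with pytest.raises(TrajkitError):
            buried_surface_area(traj, a, b)
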