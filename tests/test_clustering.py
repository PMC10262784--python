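import numpy as np
import pytest

from trajkit._geom import rotation_about_axis
from trajkit.clustering import (
    cluster_center,
    label_clusters,
    pairwise_rmsd_matrix,
    qt_cluster,
    rmsd_to_reference,
)
from trajkit.dynamics import kabsch_superpose
from trajkit.errors import TrajkitError
from trajkit.model_io import Trajectory, resolve_selection
from trajkit.synthetic import (
    TwoStateSpec,
    build_ideal_helix,
    build_peptide,
    simulate_two_state,
    ALPHA_HELIX,
    BETA_STRAND,
)


def brute_force_qt(m, cutoff, min_size_frac=0.01):
    """Exhaustive QT oracle: every round enumerates every unassigned seed."""
    t = m.shape[0]
    unassigned = set(range(t))
    clusters = []
    while unassigned:
        best = None
        for seed in sorted(unassigned):
            cand = [j for j in sorted(unassigned) if m[seed, j] <= cutoff]
            if best is None or len(cand) > len(best):
                best = cand
        if len(best) < min_size_frac * t:
            break
        clusters.append(best)
        unassigned -= set(best)
    return clusters, sorted(unassigned)


def random_rmsd_like(rng, t):
    """Symmetric, zero-diagonal, non-negative toy matrix."""
    a = rng.uniform(0.0, 4.0, (t, t))
    m = (a + a.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


class TestPairwiseMatrix:
    def test_rigid_copies_are_indistinguishable(self, helix12):
        rng = np.random.default_rng(2)
        frames = []
        for _ in range(8):
            rot = rotation_about_axis(rng.standard_normal(3), rng.uniform(0, 360))
            frames.append(helix12.coords @ rot.T + rng.uniform(-5, 5, 3))
        traj = Trajectory(helix12, np.array(frames), 250.0)
        m = pairwise_rmsd_matrix(traj, resolve_selection(helix12, "all"))
        assert m.max() < 1e-6

    def test_symmetric_zero_diagonal(self, helix10_traj):
        m = pairwise_rmsd_matrix(
            helix10_traj, resolve_selection(helix10_traj.topology, "name CA")
        )
        assert np.allclose(m, m.T, atol=1e-9)
        assert np.allclose(np.diag(m), 0.0)

    def test_matches_per_pair_kabsch(self, helix10_traj):
        sel = resolve_selection(helix10_traj.topology, "name CA")
        m = pairwise_rmsd_matrix(helix10_traj, sel)
        idx = sel.indices
        rng = np.random.default_rng(0)
        for _ in range(30):
            i, j = rng.integers(0, helix10_traj.n_frames, 2)
            if i == j:
                continue
            direct = kabsch_superpose(
                helix10_traj.frames[i, idx], helix10_traj.frames[j, idx]
            ).rmsd
            assert m[i, j] == pytest.approx(direct, abs=1e-9)


class TestQTCluster:
    def test_two_tight_groups(self):
        rng = np.random.default_rng(3)
        pts = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(10, 0.1, 20)])
        m = np.abs(pts[:, None] - pts[None, :])
        cs = qt_cluster(m, cutoff=1.0)
        assert len(cs.clusters) == 2
        assert cs.rejected.size == 0
        assert sorted(len(c.members) for c in cs.clusters) == [20, 30]

    def test_identical_frames_form_one_full_cluster(self):
        m = np.zeros((15, 15))
        cs = qt_cluster(m, cutoff=0.5)
        assert len(cs.clusters) == 1
        assert cs.clusters[0].frequency == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_oracle(self, seed):
        import warnings

        rng = np.random.default_rng(seed)
        m = random_rmsd_like(rng, 50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # random matrices may reject > 5%
            cs = qt_cluster(m, cutoff=1.5, min_size_frac=0.04)
        oracle_clusters, oracle_rejected = brute_force_qt(m, 1.5, 0.04)
        assert [c.members.tolist() for c in cs.clusters] == oracle_clusters
        assert cs.rejected.tolist() == oracle_rejected

    def test_partition_invariants(self):
        import warnings

        rng = np.random.default_rng(11)
        m = random_rmsd_like(rng, 40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # random matrices may reject > 5%
            cs = qt_cluster(m, cutoff=1.0, min_size_frac=0.05)
        all_frames = np.concatenate([c.members for c in cs.clusters] + [cs.rejected])
        assert sorted(all_frames.tolist()) == list(range(40))
        freq_total = sum(c.frequency for c in cs.clusters) + cs.rejection_rate
        assert freq_total == pytest.approx(1.0, abs=1e-12)
        for c in cs.clusters:
            assert np.all(m[c.seed, c.members] <= 1.0 + 1e-12)

    def test_frame_order_invariance_on_separated_groups(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate([rng.normal(0, 0.05, 25), rng.normal(8, 0.05, 15)])
        m = np.abs(pts[:, None] - pts[None, :])
        cs = qt_cluster(m, cutoff=1.0)
        perm = rng.permutation(40)
        mp = m[np.ix_(perm, perm)]
        csp = qt_cluster(mp, cutoff=1.0)
        orig = {frozenset(c.members.tolist()) for c in cs.clusters}
        back = {frozenset(perm[c.members].tolist()) for c in csp.clusters}
        assert orig == back

    def test_rejection_warning_above_5_percent(self):
        rng = np.random.default_rng(5)
        pts = np.concatenate([rng.normal(0, 0.05, 40), rng.normal(8, 0.05, 3),
                              np.array([20.0, 30.0, 40.0])])
        m = np.abs(pts[:, None] - pts[None, :])
        with pytest.warns(UserWarning, match="rejection rate"):
            cs = qt_cluster(m, cutoff=1.0, min_size_frac=0.1)
        assert cs.rejection_rate > 0.05

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(TrajkitError):
            qt_cluster(np.zeros((4, 4)), cutoff=0.0)


class TestClusterCenter:
    def test_singleton(self):
        m = np.zeros((3, 3))
        assert cluster_center([2], m) == 2

    def test_middle_of_a_line(self):
        pts = np.array([0.0, 1.0, 2.0])
        m = np.abs(pts[:, None] - pts[None, :])
        assert cluster_center([0, 1, 2], m) == 1

    def test_matches_row_sum_argmin(self):
        rng = np.random.default_rng(6)
        m = random_rmsd_like(rng, 25)
        members = list(range(20))
        c = cluster_center(members, m)
        sums = m[np.ix_(members, members)].sum(axis=1)
        assert c == members[int(np.argmin(sums))]


class TestReferenceComparison:
    def test_identical_structures_have_zero_rmsd(self, helix12):
        assert rmsd_to_reference(helix12, helix12) == pytest.approx(0.0, abs=1e-9)

    def test_single_atom_displacement_closed_form(self):
        s = build_ideal_helix(13)  # 52 backbone atoms
        moved = s.copy()
        moved.coords[10] += (0.0, 0.0, 1.0)
        n = s.n_atoms
        r = rmsd_to_reference(moved, s)
        # optimal alignment can only reduce the naive 1/sqrt(N) displacement
        naive = 1.0 / np.sqrt(n)
        assert 0.95 * naive <= r <= naive
        # numerical verification against an unconstrained rigid-fit oracle
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        x = moved.coords - moved.coords.mean(0)
        y = s.coords - s.coords.mean(0)

        def loss(p):
            rot = Rotation.from_rotvec(p[:3]).as_matrix()
            return np.sqrt(((x @ rot.T + p[3:] - y) ** 2).sum(1).mean())

        best = minimize(loss, np.zeros(6), method="Nelder-Mead",
                        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        assert r == pytest.approx(best.fun, abs=1e-5)

    def test_unpairable_residue_listed(self, helix12):
        short = build_ideal_helix(6)
        with pytest.raises(TrajkitError, match="unpairable"):
            rmsd_to_reference(helix12, short)

    def test_labels_flip_with_planted_state(self):
        state_a = build_peptide([ALPHA_HELIX] * 12)
        state_b = build_peptide([ALPHA_HELIX] * 7 + [BETA_STRAND] * 5)
        traj = simulate_two_state(TwoStateSpec(state_a, state_b, 0.4, seed=9),
                                  80, jitter=0.05)
        sel = resolve_selection(traj.topology, "backbone")
        m = pairwise_rmsd_matrix(traj, sel)
        cs = qt_cluster(m, cutoff=1.0)
        recs = label_clusters(traj, cs, {"A": state_a, "B": state_b})
        labels = np.array(traj.metadata["planted"]["labels"])
        assert len(recs) == 2
        for rec, c in zip(recs, cs.clusters):
            majority = "B" if labels[c.members].mean() > 0.5 else "A"
            assert rec["label"] == majority
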