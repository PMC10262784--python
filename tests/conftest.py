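import numpy as np
import pytest

from trajkit.model_io import Structure, Trajectory, resolve_selection
from trajkit.synthetic import (
    FluctuationSpec,
    TwoStateSpec,
    build_ideal_helix,
    build_peptide,
    simulate_trajectory,
    simulate_two_state,
    ALPHA_HELIX,
    BETA_STRAND,
)


@pytest.fixture(scope="session")
def helix12() -> Structure:
    return build_ideal_helix(12)


@pytest.fixture(scope="session")
def helix10_traj() -> Trajectory:
    """Small fluctuation trajectory around a 10-residue helix."""
    base = build_ideal_helix(10)
    spec = FluctuationSpec(per_residue_amplitude=0.4, seed=11)
    return simulate_trajectory(base, spec, n_frames=200)


@pytest.fixture(scope="session")
def two_state_mixture() -> Trajectory:
    """Helix vs helix-with-extended-tail mixture, occupancy_b = 0.3.

    The two conformers differ in the last 6 residues, so tail dihedrals,
    tail distances and whole-chain clustering all separate the states.
    """
    state_a = build_peptide([ALPHA_HELIX] * 16)
    state_b = build_peptide([ALPHA_HELIX] * 10 + [BETA_STRAND] * 6)
    spec = TwoStateSpec(state_a, state_b, occupancy_b=0.3, seed=7)
    return simulate_two_state(spec, n_frames=600, jitter=0.05)


@pytest.fixture()
def ca_selection():
    def _sel(obj):
        top = obj.topology if isinstance(obj, Trajectory) else obj
        return resolve_selection(top, "name CA")

    return _sel


def rigid_transform(rng: np.random.Generator):
    """Random proper rotation + translation (helper for property tests)."""
    from trajkit._geom import rotation_about_axis

    axis = rng.standard_normal(3)
    rot = rotation_about_axis(axis, rng.uniform(0.0, 360.0))
    trans = rng.uniform(-20.0, 20.0, 3)
    return rot, trans
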