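"""Synthetic structures and trajectories with planted, known ground truth.

Real microsecond MD trajectories of a kinase-ubiquitin complex are far too
expensive to regenerate and are rarely redistributable, so every analysis
stage in this package is validated against synthetic trajectories whose
statistical properties are planted by construction:

* per-residue harmonic fluctuation amplitudes (recoverable by RMSF),
* inter-residue correlations via shared latent factors (recoverable by the
  normalized covariance matrix),
* two-state conformational mixtures with a stated minor-state occupancy
  (recoverable by QT clustering and near-reference Ramachandran fractions),
* ideal secondary-structure segments (recoverable by the assigner).

The displacement model is Gaussian and independent between frames — the
analyses consume per-frame coordinates only, so temporal realism is not
needed; the "block" switching mode exists to exercise moving averages.
No force field, thermostat or solvent is involved and no physical realism
is claimed.

Amplitude convention: ``per_residue_amplitude`` is the expected RMSF of the
residue in Angstrom, i.e. displacements are iid Gaussian per axis with
standard deviation a/sqrt(3) so that sqrt(<|d|^2>) = a.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._geom import place_atom, rotation_about_axis
from .errors import TrajkitError
from .model_io import (
    AtomRecord,
    Structure,
    Trajectory,
    assign_masses_radii,
)

# Backbone internal coordinates (Engh-Huber-style averages), Angstrom/degrees.
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

ALPHA_HELIX = (-57.0, -47.0)
BETA_STRAND = (-135.0, 135.0)


def build_peptide(
    phi_psi: Sequence[tuple[float, float]],
    chain_id: str = "A",
    start_res: int = 1,
    residue_names: Sequence[str] | str = "ALA",
    omega: float = 180.0,
) -> Structure:
    """Build an N/CA/C/O backbone from a per-residue (phi, psi) sequence.

    phi of the first residue is undefined and ignored. Masses and vdW
    radii are assigned on the returned structure.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise TrajkitError("need at least one residue")
    if isinstance(residue_names, str):
        residue_names = [residue_names] * n_res
    if len(residue_names) != n_res:
        raise TrajkitError("residue_names length must match phi_psi")

    ncac: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    ncac.append((n0, ca0, c0))
    for i in range(n_res - 1):
        n_i, ca_i, c_i = ncac[i]
        psi_i = phi_psi[i][1]
        phi_next = phi_psi[i + 1][0]
        n_next = place_atom(n_i, ca_i, c_i, _B_C_N, _A_CA_C_N, psi_i)
        ca_next = place_atom(ca_i, c_i, n_next, _B_N_CA, _A_C_N_CA, omega)
        c_next = place_atom(c_i, n_next, ca_next, _B_CA_C, _A_N_CA_C, phi_next)
        ncac.append((n_next, ca_next, c_next))

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1
    for i, (n_i, ca_i, c_i) in enumerate(ncac):
        if i < n_res - 1:
            o_i = place_atom(ncac[i + 1][0], ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        else:
            o_i = place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, phi_psi[i][1] + 180.0)
        for name, xyz in (("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i)):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    element=name[0],
                    residue_name=residue_names[i],
                    residue_index=start_res + i,
                    chain_id=chain_id,
                )
            )
            coords.append(xyz)
            serial += 1
    return assign_masses_radii(Structure(atoms, np.array(coords)))


def build_ideal_helix(
    n_res: int, chain_id: str = "A", start_res: int = 1
) -> Structure:
    """Ideal alpha-helical backbone (phi = -57, psi = -47, omega = 180)."""
    if n_res < 4:
        raise TrajkitError("an ideal helix needs at least 4 residues")
    return build_peptide([ALPHA_HELIX] * n_res, chain_id, start_res)


def build_ideal_strand(
    n_res: int, chain_id: str = "A", start_res: int = 1
) -> Structure:
    """Ideal extended strand backbone (phi = -135, psi = 135)."""
    if n_res < 2:
        raise TrajkitError("a strand needs at least 2 residues")
    return build_peptide([BETA_STRAND] * n_res, chain_id, start_res)


def build_ideal_hairpin(n_strand: int = 5, chain_id: str = "A") -> Structure:
    """Two-stranded antiparallel beta hairpin joined by a type II' turn.

    The strands zip up through backbone hydrogen bonds, so interior
    residues are assigned extended-strand (E) codes.
    """
    if n_strand < 3:
        raise TrajkitError("hairpin strands need at least 3 residues")
    turn = [(60.0, -120.0), (-80.0, 0.0)]  # type II' tight turn
    pp = [BETA_STRAND] * n_strand + turn + [BETA_STRAND] * n_strand
    return build_peptide(pp, chain_id=chain_id)


def _merge(a: Structure, b: Structure) -> Structure:
    atoms = [
        AtomRecord(**{**vars(rec)}) for rec in (*a.atoms, *b.atoms)
    ]
    for s, rec in enumerate(atoms, start=1):
        rec.serial = s
    return Structure(atoms, np.vstack([a.coords, b.coords]))


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    ax = vt[0]
    return ax if ax[0] >= 0 else -ax


def build_two_chain_complex(
    n_res_a: int,
    n_res_b: int,
    gap: float = 4.0,
    seed: int = 0,
) -> Structure:
    """Two helical chains (ids A and U) separated by a target contact gap.

    The minimum inter-chain heavy-atom distance comes out within 0.5 A of
    ``gap``. The seed sets the spin of chain U about its own axis, so the
    construct is deterministic per seed.
    """
    if n_res_a < 4 or n_res_b < 4:
        raise TrajkitError("chains need at least 4 residues each")
    if gap < 0:
        raise TrajkitError("gap must be non-negative")
    a = build_ideal_helix(n_res_a, chain_id="A")
    b = build_ideal_helix(n_res_b, chain_id="U")
    rng = np.random.default_rng(seed)
    ax_a = _principal_axis(a.coords)
    ax_b = _principal_axis(b.coords)
    # align chain U's axis with chain A's, spin it, then offset sideways
    v = np.cross(ax_b, ax_a)
    s, c = np.linalg.norm(v), float(np.dot(ax_b, ax_a))
    if s > 1e-12:
        k = v / s
        rot = rotation_about_axis(k, np.degrees(np.arctan2(s, c)))
    else:
        rot = np.eye(3) if c > 0 else rotation_about_axis([0.0, 0.0, 1.0], 180.0)
    spin = rotation_about_axis(ax_a, float(rng.uniform(0.0, 360.0)))
    bc = (b.coords - b.coords.mean(0)) @ rot.T @ spin.T + a.coords.mean(0)
    # sideways offset direction perpendicular to the common axis
    perp = np.cross(ax_a, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(ax_a, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    offset = gap + 10.0
    for _ in range(50):
        trial = bc + offset * perp
        dmin = _min_interchain_distance(a.coords, trial)
        if abs(dmin - gap) <= 0.4:
            break
        offset += gap - dmin
    b2 = b.with_coords(bc + offset * perp)
    return _merge(a, b2)


def _min_interchain_distance(xa: np.ndarray, xb: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    return float(cKDTree(xa).query(xb)[0].min())


# ---------------------------------------------------------------------------
# Fluctuation trajectories
# ---------------------------------------------------------------------------

@dataclass
class FluctuationSpec:
    """Planted per-residue fluctuation statistics.

    per_residue_amplitude: scalar (all residues) or mapping keyed by
        (chain, resid) [or bare resid]; the value is the residue's expected
        RMSF in Angstrom.
    correlation_blocks: (residue_set, residue_set, target_correlation)
        triples; each residue may appear in at most one block. Correlations
        are planted through a shared latent 3-vector per block.
    rigid_body: optional (rotation_amplitude_deg, translation_amplitude_A)
        global rigid noise applied to every frame, removable by alignment.
    """

    per_residue_amplitude: float | Mapping = 0.3
    correlation_blocks: list[tuple] = field(default_factory=list)
    rigid_body: tuple[float, float] | None = None
    seed: int = 0


def _residue_amplitudes(spec: FluctuationSpec, residues: list) -> np.ndarray:
    amp = spec.per_residue_amplitude
    if isinstance(amp, (int, float)):
        a = np.full(len(residues), float(amp))
    else:
        a = np.zeros(len(residues))
        for i, rid in enumerate(residues):
            if rid in amp:
                a[i] = float(amp[rid])
            elif rid[1] in amp:
                a[i] = float(amp[rid[1]])
    if np.any(a < 0):
        raise TrajkitError("fluctuation amplitudes must be >= 0")
    return a


def _normalize_residue_set(rset, residues: list) -> list[int]:
    out = []
    for r in rset:
        key = tuple(r) if isinstance(r, (tuple, list)) else r
        matches = [
            i for i, rid in enumerate(residues)
            if rid == key or rid[1] == key
        ]
        if not matches:
            raise TrajkitError(f"residue {r} not found in topology")
        out.extend(matches)
    return sorted(set(out))


def _implied_correlation(n_res: int, blocks) -> np.ndarray:
    corr = np.eye(n_res)
    for idx_a, idx_b, c in blocks:
        sgn = {i: 1.0 for i in idx_a}
        for i in idx_b:
            sgn[i] = np.sign(c) if c != 0 else 1.0
        members = sorted(sgn)
        for i in members:
            for j in members:
                if i != j:
                    corr[i, j] = abs(c) * sgn[i] * sgn[j]
    return corr


def simulate_trajectory(
    base: Structure,
    spec: FluctuationSpec,
    n_frames: int,
    frame_dt: float = 250.0,
) -> Trajectory:
    """Gaussian fluctuation trajectory around a base structure.

    Frame f is R_f (base + displacement_f) + t_f: residue-rigid Gaussian
    displacements with the planted amplitudes and correlations, plus the
    optional global rigid noise. Bitwise reproducible under a fixed seed.
    """
    if n_frames < 2:
        raise TrajkitError("need at least 2 frames")
    residues = base.residue_ids()
    n_res = len(residues)
    amps = _residue_amplitudes(spec, residues)

    blocks = []
    claimed: set[int] = set()
    for rset_a, rset_b, c in spec.correlation_blocks:
        if abs(c) > 1.0:
            raise TrajkitError(f"target correlation {c} outside [-1, 1]")
        ia = _normalize_residue_set(rset_a, residues)
        ib = _normalize_residue_set(rset_b, residues)
        overlap = claimed.intersection(ia + ib)
        if overlap or set(ia) & set(ib):
            raise TrajkitError(
                "unsatisfiable correlation spec: residue in multiple blocks"
            )
        claimed.update(ia + ib)
        blocks.append((ia, ib, float(c)))
    implied = _implied_correlation(n_res, blocks)
    if np.linalg.eigvalsh(implied).min() < -1e-9:
        raise TrajkitError("unsatisfiable correlation spec: implied matrix not PSD")

    rng = np.random.default_rng(spec.seed)
    latent = rng.standard_normal((n_frames, max(len(blocks), 1), 3))
    noise = rng.standard_normal((n_frames, n_res, 3))
    disp = noise.copy()
    for b, (ia, ib, c) in enumerate(blocks):
        w_shared = np.sqrt(abs(c))
        w_own = np.sqrt(1.0 - abs(c))
        for i in ia:
            disp[:, i, :] = w_shared * latent[:, b, :] + w_own * noise[:, i, :]
        sgn = np.sign(c) if c != 0 else 1.0
        for i in ib:
            disp[:, i, :] = sgn * w_shared * latent[:, b, :] + w_own * noise[:, i, :]
    disp *= (amps / np.sqrt(3.0))[None, :, None]

    res_of_atom = np.array(
        [residues.index(a.residue_id) for a in base.atoms], dtype=int
    )
    frames = base.coords[None, :, :] + disp[:, res_of_atom, :]

    if spec.rigid_body is not None:
        rot_amp, trans_amp = spec.rigid_body
        center = base.coords.mean(0)
        axes = rng.standard_normal((n_frames, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.normal(0.0, rot_amp, n_frames)
        shifts = rng.normal(0.0, trans_amp / np.sqrt(3.0), (n_frames, 3))
        for f in range(n_frames):
            r = rotation_about_axis(axes[f], angles[f])
            frames[f] = (frames[f] - center) @ r.T + center + shifts[f]

    meta = {
        "planted": {
            "amplitudes": {str(r): float(a) for r, a in zip(residues, amps)},
            "correlation_blocks": [
                (list(map(str, [residues[i] for i in ia])),
                 list(map(str, [residues[i] for i in ib])), c)
                for ia, ib, c in blocks
            ],
            "rigid_body": spec.rigid_body,
            "seed": spec.seed,
        }
    }
    return Trajectory(base.copy(), frames, frame_dt, meta)


# ---------------------------------------------------------------------------
# Two-state mixtures
# ---------------------------------------------------------------------------

@dataclass
class TwoStateSpec:
    """A two-conformation mixture (e.g. common Ub vs the retracted Ub-CR)."""

    state_a: Structure
    state_b: Structure
    occupancy_b: float
    switching: str = "iid"  # "iid" or "block"
    dwell: int = 50  # mean state-B dwell length in frames, block mode only
    seed: int = 0


def simulate_two_state(
    spec: TwoStateSpec,
    n_frames: int,
    frame_dt: float = 250.0,
    jitter: float = 0.0,
) -> Trajectory:
    """Sample frames from a two-state mixture plus iid Gaussian jitter.

    The realized state labels and occupancy are recorded in the trajectory
    metadata so downstream recovery tests can compare against truth.
    """
    if n_frames < 2:
        raise TrajkitError("need at least 2 frames")
    if not (0.0 <= spec.occupancy_b <= 1.0):
        raise TrajkitError("occupancy_b must be in [0, 1]")
    if jitter < 0:
        raise TrajkitError("jitter must be >= 0")
    a, b = spec.state_a, spec.state_b
    key_a = [(x.chain_id, x.residue_index, x.atom_name) for x in a.atoms]
    key_b = [(x.chain_id, x.residue_index, x.atom_name) for x in b.atoms]
    if key_a != key_b:
        raise TrajkitError("state_a and state_b do not share a topology")

    rng = np.random.default_rng(spec.seed)
    p = spec.occupancy_b
    if spec.switching == "iid":
        labels = (rng.random(n_frames) < p).astype(int)
    elif spec.switching == "block":
        if spec.dwell < 1:
            raise TrajkitError("dwell must be >= 1 frame")
        # two-state Markov chain with stationary occupancy p and mean
        # state-B dwell equal to `dwell`
        p_ba = 1.0 / spec.dwell
        p_ab = p_ba * p / max(1.0 - p, 1e-12)
        p_ab = min(p_ab, 1.0)
        labels = np.empty(n_frames, dtype=int)
        labels[0] = int(rng.random() < p)
        u = rng.random(n_frames)
        for f in range(1, n_frames):
            if labels[f - 1] == 1:
                labels[f] = 0 if u[f] < p_ba else 1
            else:
                labels[f] = 1 if u[f] < p_ab else 0
    else:
        raise TrajkitError(f"unknown switching mode {spec.switching!r}")

    stack = np.stack([a.coords, b.coords])
    frames = stack[labels]
    if jitter > 0:
        frames = frames + rng.normal(0.0, jitter, frames.shape)
    meta = {
        "planted": {
            "occupancy_b": p,
            "realized_occupancy_b": float(labels.mean()),
            "labels": labels.tolist(),
            "switching": spec.switching,
            "jitter": jitter,
            "seed": spec.seed,
        }
    }
    return Trajectory(a.copy(), frames, frame_dt, meta)

# ---------------------------------------------------------------------------
# Packaged synthetic study pair: flexible vs stabilized complex
# ---------------------------------------------------------------------------

@dataclass
class StudyPair:
    """Two synthetic kinase-substrate trajectories with planted contrasts.

    ``wt`` emulates the flexible wild-type-like complex: large jitter, the
    substrate mostly in the "common" pose with a minor retracted ("CR")
    population. ``variant`` emulates the stabilized complex: small jitter
    and a dominant CR population. The planted qualitative contrasts are
    listed in ``ground_truth``.
    """

    wt: Trajectory
    variant: Trajectory
    references: dict  # label -> chain-U-only reference Structure
    ground_truth: dict


# Substrate-chain design, ubiquitin-like author numbering 46..76:
# a helical body (46-70) and a 6-residue tail (71-76). The "common" pose has
# an extended tail; the "CR" pose chains two tight turns so the tail curls
# back (shorter 46-76 distance) and is assigned turn (T) codes at 73-75.
_TAIL_COMMON = [BETA_STRAND] * 6
_TAIL_CR = [BETA_STRAND, (-60.0, -30.0), (-90.0, 0.0),
            (-60.0, -30.0), (-90.0, 0.0), (-135.0, 0.0)]


def _substrate_names() -> list[str]:
    names = ["ALA"] * 31
    names[65 - 46] = "SER"
    names[76 - 46] = "GLY"
    return names


def _axis_and_center(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = coords.mean(0)
    ax = _principal_axis(coords)
    return ax, center


def _place_substrate(
    kinase: Structure,
    substrate: Structure,
    face_residue: int,
    face_toward: bool,
    gap: float,
) -> Structure:
    """Align the substrate helix axis with the kinase axis, spin it so the
    face residue points toward (or away from) the kinase, and set the
    contact gap."""
    helix_ca = np.array([
        substrate.coords[substrate.find_atom("U", r, "CA")] for r in range(46, 71)
    ])
    kin_ca = np.array([
        kinase.coords[i] for i, a in enumerate(kinase.atoms) if a.atom_name == "CA"
    ])
    ax_k, cen_k = _axis_and_center(kin_ca)
    ax_u, cen_u = _axis_and_center(helix_ca)
    v = np.cross(ax_u, ax_k)
    s, c = np.linalg.norm(v), float(np.dot(ax_u, ax_k))
    if s > 1e-12:
        rot = rotation_about_axis(v / s, np.degrees(np.arctan2(s, c)))
    else:
        rot = np.eye(3) if c > 0 else rotation_about_axis([0.0, 0.0, 1.0], 180.0)
    coords = (substrate.coords - cen_u) @ rot.T

    perp = np.cross(ax_k, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(ax_k, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    # radial direction of the face residue's CA around the helix axis
    i65 = substrate.find_atom("U", face_residue, "CA")
    r = coords[i65] - coords[:100].mean(0)
    r = r - np.dot(r, ax_k) * ax_k
    r /= np.linalg.norm(r)
    target = -perp if face_toward else perp
    cross = np.dot(np.cross(r, target), ax_k)
    spin = np.degrees(np.arctan2(cross, np.dot(r, target)))
    coords = coords @ rotation_about_axis(ax_k, spin).T

    offset = gap + 12.0
    base = coords + cen_k
    for _ in range(60):
        trial = base + offset * perp
        dmin = _min_interchain_distance(kinase.coords, trial)
        if abs(dmin - gap) <= 0.3:
            break
        offset += gap - dmin
    return substrate.with_coords(base + offset * perp)


def make_study_pair(
    seed: int = 0,
    n_frames: int = 160,
    frame_dt: float = 250.0,
    occupancy_cr_wt: float = 0.25,
    occupancy_cr_variant: float = 0.80,
    jitter_wt: float = 0.45,
    jitter_variant: float = 0.25,
    gap: float = 3.2,
) -> StudyPair:
    """Build the packaged flexible-vs-stabilized synthetic trajectory pair.

    Planted contrasts (variant relative to wt): lower RMSF (smaller jitter
    and a more one-sided mixture), higher CR-state occupancy (hence higher
    CR-like cluster frequency and tail-turn occupancy), shorter 46-76
    retraction distance on average, and higher Ser65-analog SASA (the CR
    pose turns residue 65 away from the interface).
    """
    kinase = build_peptide([ALPHA_HELIX] * 24, chain_id="A", start_res=400)
    names = _substrate_names()
    u_common = build_peptide(
        [ALPHA_HELIX] * 25 + _TAIL_COMMON, chain_id="U", start_res=46,
        residue_names=names,
    )
    u_cr = build_peptide(
        [ALPHA_HELIX] * 25 + _TAIL_CR, chain_id="U", start_res=46,
        residue_names=names,
    )
    u_common = _place_substrate(kinase, u_common, 65, face_toward=True, gap=gap)
    u_cr = _place_substrate(kinase, u_cr, 65, face_toward=False, gap=gap)
    state_common = assign_masses_radii(_merge(kinase, u_common))
    state_cr = assign_masses_radii(_merge(kinase, u_cr))

    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    wt = simulate_two_state(
        TwoStateSpec(state_common, state_cr, occupancy_cr_wt, seed=int(seeds[0])),
        n_frames, frame_dt, jitter=jitter_wt,
    )
    variant = simulate_two_state(
        TwoStateSpec(state_common, state_cr, occupancy_cr_variant, seed=int(seeds[1])),
        n_frames, frame_dt, jitter=jitter_variant,
    )
    references = {
        "common": assign_masses_radii(u_common),
        "CR": assign_masses_radii(u_cr),
    }
    d_common = float(np.linalg.norm(
        u_common.coords[u_common.find_atom("U", 46, "CA")]
        - u_common.coords[u_common.find_atom("U", 76, "CA")]
    ))
    d_cr = float(np.linalg.norm(
        u_cr.coords[u_cr.find_atom("U", 46, "CA")]
        - u_cr.coords[u_cr.find_atom("U", 76, "CA")]
    ))
    ground_truth = {
        "occupancy_cr": {"wt": occupancy_cr_wt, "variant": occupancy_cr_variant},
        "realized_occupancy_cr": {
            "wt": wt.metadata["planted"]["realized_occupancy_b"],
            "variant": variant.metadata["planted"]["realized_occupancy_b"],
        },
        "jitter": {"wt": jitter_wt, "variant": jitter_variant},
        "retraction_distance_by_state": {"common": d_common, "CR": d_cr},
        "contrasts": [
            "variant has lower mean substrate RMSF",
            "variant has higher CR-like cluster frequency",
            "variant has shorter mean 46-76 distance",
            "variant has higher mean Ser65 SASA",
            "variant has higher tail turn occupancy",
        ],
        "seed": seed,
        "n_frames": n_frames,
        "frame_dt": frame_dt,
    }
    return StudyPair(wt=wt, variant=variant, references=references,
                     ground_truth=ground_truth)
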