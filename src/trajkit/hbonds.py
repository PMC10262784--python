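"""Geometric hydrogen-bond detection and per-frame counting.

Criteria follow common practice for MD post-analysis: a donor-heavy-atom to
acceptor distance cutoff (default 3.5 A) plus, when an explicit hydrogen is
present, a D-H...A linearity screen (default deviation <= 30 deg from 180).
On heavy-atom-only trajectories the distance criterion alone applies. Both
cutoffs are configuration-exposed and echoed in reports, since upstream
tools differ in their defaults.

Donor/acceptor chemistry is a fixed table (no pKa logic): the backbone
amide N donates (except proline), the backbone carbonyl O accepts, and
standard side-chain N/O atoms take their textbook roles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import TrajkitError
from .model_io import Selection, Structure, Trajectory

# side-chain donor / acceptor atom names by residue
SIDECHAIN_DONORS = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": set(),
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 3.5  # donor heavy atom to acceptor, Angstrom
    max_dha_angle_dev: float = 30.0  # deviation of D-H...A from linear, deg
    use_angle: bool = True  # ignored when no hydrogen is attached

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise TrajkitError("distance cutoff must be positive")
        if not (0.0 <= self.max_dha_angle_dev <= 180.0):
            raise TrajkitError("angle deviation must be in [0, 180]")


class HBond(NamedTuple):
    donor: int  # atom index
    acceptor: int  # atom index
    distance: float  # Angstrom
    angle_dev: float | None  # deg deviation from linear, None without H


def _is_donor(atom) -> bool:
    if atom.atom_name == "N" and atom.residue_name != "PRO":
        return True
    return atom.atom_name in SIDECHAIN_DONORS.get(atom.residue_name, ())


def _is_acceptor(atom) -> bool:
    if atom.atom_name == "O" or atom.atom_name == "OXT":
        return True
    return atom.atom_name in SIDECHAIN_ACCEPTORS.get(atom.residue_name, ())


def _attached_hydrogens(frame: Structure, donor_idx: int) -> list[int]:
    d = frame.atoms[donor_idx]
    out = []
    for i, a in enumerate(frame.atoms):
        if (
            a.element == "H"
            and a.residue_id == d.residue_id
            and np.linalg.norm(frame.coords[i] - frame.coords[donor_idx]) < 1.3
        ):
            out.append(i)
    return out


def detect_hbonds(
    frame: Structure,
    donors: Selection,
    acceptors: Selection,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """Hydrogen bonds from donor-capable atoms in ``donors`` to
    acceptor-capable atoms in ``acceptors``.

    Each (donor, acceptor) pair is reported at most once; intra-residue
    pairs are skipped. Output is ordered by (donor serial, acceptor serial).
    """
    if len(donors) == 0 or len(acceptors) == 0:
        raise TrajkitError("empty donor or acceptor selection")
    d_idx = [i for i in donors.indices if _is_donor(frame.atoms[i])]
    a_idx = [i for i in acceptors.indices if _is_acceptor(frame.atoms[i])]
    if not d_idx or not a_idx:
        return []
    a_arr = np.asarray(a_idx)
    tree = cKDTree(frame.coords[a_arr])
    bonds: list[HBond] = []
    for di in d_idx:
        hs = _attached_hydrogens(frame, di)
        near = tree.query_ball_point(frame.coords[di], criteria.max_da_distance)
        for k in near:
            ai = int(a_arr[k])
            if frame.atoms[ai].residue_id == frame.atoms[di].residue_id:
                continue
            dist = float(np.linalg.norm(frame.coords[ai] - frame.coords[di]))
            if hs and criteria.use_angle:
                devs = []
                for hi in hs:
                    v1 = frame.coords[di] - frame.coords[hi]
                    v2 = frame.coords[ai] - frame.coords[hi]
                    c = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
                    devs.append(180.0 - ang)
                dev = min(devs)
                if dev > criteria.max_dha_angle_dev:
                    continue
            else:
                dev = None
            bonds.append(HBond(di, ai, dist, dev))
    bonds.sort(key=lambda b: (frame.atoms[b.donor].serial,
                              frame.atoms[b.acceptor].serial))
    return bonds


def hbond_count_series(
    traj: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    criteria: HBondCriteria = HBondCriteria(),
) -> np.ndarray:
    """Per-frame count of hydrogen bonds between two selections.

    Both directions are counted: donors in A with acceptors in B and
    donors in B with acceptors in A; a pair satisfying both roles is
    counted once.
    """
    out = np.empty(traj.n_frames, dtype=int)
    for f, frame in enumerate(traj.iter_frames()):
        pairs = set()
        for b in detect_hbonds(frame, sel_a, sel_b, criteria):
            pairs.add((b.donor, b.acceptor))
        for b in detect_hbonds(frame, sel_b, sel_a, criteria):
            pairs.add((b.donor, b.acceptor))
        out[f] = len(pairs)
    return out


def hbond_occupancy_table(
    traj: Trajectory,
    sel_a: Selection,
    sel_b: Selection,
    criteria: HBondCriteria = HBondCriteria(),
) -> dict[tuple[int, int], float]:
    """Fraction of frames each (donor, acceptor) atom pair is bonded."""
    counts: dict[tuple[int, int], int] = {}
    for frame in traj.iter_frames():
        pairs = set()
        for b in detect_hbonds(frame, sel_a, sel_b, criteria):
            pairs.add((b.donor, b.acceptor))
        for b in detect_hbonds(frame, sel_b, sel_a, criteria):
            pairs.add((b.donor, b.acceptor))
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
    return {p: c / traj.n_frames for p, c in counts.items()}
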