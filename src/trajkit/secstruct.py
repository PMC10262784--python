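"""DSSP-style secondary-structure assignment and occupancy statistics.

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
model,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond being assigned when E < -0.5 kcal/mol. Amide hydrogens are
reconstructed when absent: 1.01 A from N, anti to the bisector of the
N->C(prev) and N->CA bond directions (the first residue of a chain has no
i-1 carbonyl and therefore no donor). From the bond pattern, n-turns
(i -> i+3/4/5) yield 3-10 (G), alpha (H) and pi (I) helices, bridge
ladders yield strand (E) and isolated bridge (B), and turn/bend residues
yield T; everything else is coil (C). Code priority: H > E > B > G > I >
T > C.

The assignment is purely geometric, deterministic and invariant to global
rigid motion. Hydrogen bonds are evaluated within each chain (inter-chain
sheets are not assigned; the fixtures and analyses here are per-chain).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geom import angle
from .errors import TrajkitError
from .model_io import Structure, Trajectory

KS_COUPLING = 0.084 * 332.0  # kcal/mol * Angstrom
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_NH_BOND = 1.01  # Angstrom
_CHAIN_BREAK = 2.5  # C(i-1)-N(i) distance beyond which the chain is broken

SS_CODES = ("H", "G", "I", "E", "B", "T", "C")


@dataclass(frozen=True)
class SSTimeline:
    """Per-frame, per-residue secondary-structure codes."""

    codes: np.ndarray  # (T, n_res) of single characters
    labels: list  # (chain, resid)
    frame_dt: float

    @property
    def n_frames(self) -> int:
        return int(self.codes.shape[0])


def _chain_residues(structure: Structure) -> dict[str, list[tuple[int, dict]]]:
    """Per chain: ordered (resid, {atom_name: coord}) with backbone atoms."""
    chains: dict[str, dict[int, dict]] = {}
    order: dict[str, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        ch = chains.setdefault(a.chain_id, {})
        if a.residue_index not in ch:
            ch[a.residue_index] = {"name": a.residue_name}
            order.setdefault(a.chain_id, []).append(a.residue_index)
        if a.atom_name in ("N", "CA", "C", "O", "H", "HN", "H1"):
            ch[a.residue_index][a.atom_name] = structure.coords[i]
    return {
        cid: [(r, chains[cid][r]) for r in order[cid]] for cid in order
    }


def _ks_energy(n_d, h_d, c_a, o_a) -> float:
    r_on = np.linalg.norm(o_a - n_d)
    r_ch = np.linalg.norm(c_a - h_d)
    r_oh = np.linalg.norm(o_a - h_d)
    r_cn = np.linalg.norm(c_a - n_d)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return 0.0  # overlapping atoms: not a credible bond
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _assign_chain(residues: list[tuple[int, dict]]) -> list[str]:
    n = len(residues)
    codes = ["C"] * n
    ok = [all(k in res for k in ("N", "CA", "C", "O")) for _, res in residues]
    if not all(ok):
        warnings.warn(
            "residue(s) missing backbone atoms assigned coil", stacklevel=3
        )
    # donor hydrogens
    h_pos: list[np.ndarray | None] = [None] * n
    for i, (_, res) in enumerate(residues):
        if not ok[i] or res["name"] == "PRO":
            continue
        explicit = res.get("H")
        if explicit is None:
            explicit = res.get("HN")
        if explicit is not None:
            h_pos[i] = explicit
            continue
        if i == 0 or not ok[i - 1]:
            continue
        c_prev = residues[i - 1][1]["C"]
        if np.linalg.norm(res["N"] - c_prev) > _CHAIN_BREAK:
            continue
        u1 = res["N"] - c_prev
        u1 /= np.linalg.norm(u1)
        u2 = res["N"] - res["CA"]
        u2 /= np.linalg.norm(u2)
        d = u1 + u2
        d /= np.linalg.norm(d)
        h_pos[i] = res["N"] + _NH_BOND * d

    # Kabsch-Sander bonds: hb[d][a] True when NH of d donates to CO of a
    hb = np.zeros((n, n), dtype=bool)
    for d in range(n):
        if h_pos[d] is None:
            continue
        nd = residues[d][1]["N"]
        for a in range(n):
            if abs(d - a) < 2 or not ok[a]:
                continue
            res_a = residues[a][1]
            if np.linalg.norm(residues[d][1]["CA"] - res_a["CA"]) > 9.0:
                continue
            e = _ks_energy(nd, h_pos[d], res_a["C"], res_a["O"])
            if e < HBOND_ENERGY_CUTOFF:
                hb[d, a] = True

    def turn(i: int, m: int) -> bool:
        return i + m < n and hb[i + m, i]

    def mark(rng, code):
        for k in rng:
            if 0 <= k < n:
                codes[k] = code

    # lowest priority first; later marks overwrite earlier ones
    # T: interior residues of any n-turn, plus CA bends
    for i in range(n):
        for m in (3, 4, 5):
            if turn(i, m):
                mark(range(i + 1, i + m), "T")
    for i in range(2, n - 2):
        if all(ok[j] for j in (i - 2, i, i + 2)):
            # bend: CA-path direction change over i-2 -> i -> i+2 above 70 deg
            v1 = residues[i][1]["CA"] - residues[i - 2][1]["CA"]
            v2 = residues[i + 2][1]["CA"] - residues[i][1]["CA"]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0 and codes[i] == "C":
                codes[i] = "T"
    # pi then 3-10 helices
    for i in range(1, n):
        if turn(i - 1, 5) and turn(i, 5):
            mark(range(i, i + 5), "I")
    for i in range(1, n):
        if turn(i - 1, 3) and turn(i, 3):
            mark(range(i, i + 3), "G")
    # bridges and ladders
    bridges: list[tuple[int, int, str]] = []
    for i in range(n):
        for j in range(i + 3, n):
            para = (hb[j, i - 1] and hb[i + 1, j] if i >= 1 and i + 1 < n else False) or (
                hb[i, j - 1] and hb[j + 1, i] if j >= 1 and j + 1 < n else False
            )
            anti = (hb[j, i] and hb[i, j]) or (
                hb[j + 1, i - 1] and hb[i + 1, j - 1]
                if i >= 1 and j + 1 < n and j >= 1 and i + 1 < n
                else False
            )
            if para:
                bridges.append((i, j, "p"))
            elif anti:
                bridges.append((i, j, "a"))
    in_ladder = set()
    for k, (i1, j1, t1) in enumerate(bridges):
        for i2, j2, t2 in bridges[k + 1:]:
            if t1 == t2 and abs(i1 - i2) <= 1 and abs(j1 - j2) <= 1:
                in_ladder.update([(i1, j1, t1), (i2, j2, t2)])
    for b in bridges:
        code = "E" if b in in_ladder else "B"
        for k in (b[0], b[1]):
            if code == "E" or codes[k] != "E":
                codes[k] = code
    # alpha helices (highest priority)
    for i in range(1, n):
        if turn(i - 1, 4) and turn(i, 4):
            mark(range(i, i + 4), "H")
    for i in range(n):
        if not ok[i]:
            codes[i] = "C"
    return codes


def assign_secondary_structure(frame: Structure) -> tuple[list, list[str]]:
    """Assign one code per residue; returns (labels, codes) in topology order."""
    chains = _chain_residues(frame)
    labels: list = []
    codes: list[str] = []
    for cid, residues in chains.items():
        ch_codes = _assign_chain(residues)
        labels.extend((cid, r) for r, _ in residues)
        codes.extend(ch_codes)
    return labels, codes


def ss_timeline(traj: Trajectory) -> SSTimeline:
    """Secondary-structure codes for every residue of every frame."""
    if traj.n_frames < 1:
        raise TrajkitError("empty trajectory")
    labels: list | None = None
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for frame in traj.iter_frames():
            lab, codes = assign_secondary_structure(frame)
            if labels is None:
                labels = lab
            rows.append(codes)
    return SSTimeline(
        codes=np.array(rows, dtype="<U1"), labels=labels, frame_dt=traj.frame_dt
    )


def occupancy(
    timeline: SSTimeline,
    residues,
    codes,
    mode: str = "per_residue_mean",
) -> float:
    """Percent of simulation time a residue set spends in a code set.

    ``per_residue_mean``: mean over residues of the per-residue fraction of
    frames whose code is in ``codes``, as percent. ``all_residues``: percent
    of frames in which EVERY listed residue carries a code in ``codes``.
    """
    res_list = list(residues)
    if not res_list:
        raise TrajkitError("empty residue set")
    cols = []
    for r in res_list:
        key = tuple(r) if isinstance(r, (tuple, list)) else r
        matches = [
            i for i, lab in enumerate(timeline.labels)
            if lab == key or lab[1] == key
        ]
        if not matches:
            raise TrajkitError(f"residue {r} not in timeline")
        cols.extend(matches)
    code_set = set(codes)
    member = np.isin(timeline.codes[:, cols], list(code_set))
    if mode == "per_residue_mean":
        return float(member.mean(axis=0).mean() * 100.0)
    if mode == "all_residues":
        return float(member.all(axis=1).mean() * 100.0)
    raise TrajkitError(f"unknown occupancy mode {mode!r}")
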