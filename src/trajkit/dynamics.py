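"""Superposition, RMSD/RMSF and correlated motions.

The alignment convention throughout the package: a trajectory is first
superposed frame-by-frame onto a reference frame using a least-squares
(Kabsch) fit on a fit selection — conventionally the backbone C, O, N, CA
atoms of the kinase chain — and every per-frame metric is then computed in
that common frame of reference.

Per-residue covariances are mass-weighted and normalized: the displacement
of a residue is the mass-weighted mean displacement of its selected atoms,
and the matrix entry is the normalized scalar-product correlation

    C(i, j) = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)  in [-1, 1].

For CA-only selections the mass weights cancel under the normalization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import TrajkitError
from .model_io import Selection, Structure, Trajectory


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform: aligned = mobile @ rotation.T + translation."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RMSFProfile:
    labels: list  # (chain, resid) pairs, or atom indices when ungrouped
    values: np.ndarray  # Angstrom, >= 0


@dataclass(frozen=True)
class CovarianceMatrix:
    labels: list  # (chain, resid) pairs
    values: np.ndarray  # (n, n) in [-1, 1], symmetric, unit diagonal

    def entry(self, res_i, res_j) -> float:
        i = self.labels.index(tuple(res_i))
        j = self.labels.index(tuple(res_j))
        return float(self.values[i, j])


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted least-squares optimal rigid superposition (Kabsch, via SVD).

    A reflection in the raw SVD solution is corrected by flipping the sign
    of the smallest singular direction, so the rotation is always proper
    (det = +1).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise TrajkitError("mobile and reference must both be (N, 3)")
    n = mob.shape[0]
    if n < 3:
        raise TrajkitError("superposition requires at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise TrajkitError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cm = (w[:, None] * mob).sum(0) / wsum
    cr = (w[:, None] * ref).sum(0) / wsum
    mc = mob - cm
    rc = ref - cr
    h = (w[:, None] * mc).T @ rc
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(1.0, s[0]):
        raise TrajkitError("degenerate (collinear) point set: rotation ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    aligned = mc @ rot.T + cr
    rmsd = float(np.sqrt((w * ((aligned - ref) ** 2).sum(1)).sum() / wsum))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def align_trajectory(
    traj: Trajectory, fit_selection: Selection, ref_frame: int = 0
) -> Trajectory:
    """Superpose every frame onto ``ref_frame`` fitting on ``fit_selection``.

    The fitted transform of each frame is applied to ALL atoms, so
    non-fitted chains move rigidly with the fit group.
    """
    if not (0 <= ref_frame < traj.n_frames):
        raise TrajkitError(f"ref_frame {ref_frame} out of range [0, {traj.n_frames})")
    if len(fit_selection) == 0:
        raise TrajkitError("empty fit selection")
    idx = fit_selection.indices
    ref = traj.frames[ref_frame, idx]
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        sup = kabsch_superpose(traj.frames[f, idx], ref)
        out[f] = sup.apply(traj.frames[f])
    meta = dict(traj.metadata)
    meta["aligned_on"] = fit_selection.expression
    meta["ref_frame"] = ref_frame
    return Trajectory(traj.topology, out, traj.frame_dt, meta)


def rmsd_series(
    traj: Trajectory,
    selection: Selection,
    ref_frame: int = 0,
    refit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) to a reference frame over a selection.

    ``refit=True`` performs a fresh superposition on the selection for each
    frame (rigid-motion-free metric); ``refit=False`` measures in the
    current, presumably pre-aligned, coordinates.
    """
    if len(selection) == 0:
        raise TrajkitError("empty selection")
    if not (0 <= ref_frame < traj.n_frames):
        raise TrajkitError(f"ref_frame {ref_frame} out of range")
    idx = selection.indices
    ref = traj.frames[ref_frame, idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.frames[f, idx]
        if refit:
            out[f] = kabsch_superpose(mob, ref).rmsd
        else:
            out[f] = float(np.sqrt(((mob - ref) ** 2).sum(1).mean()))
    return out


def rmsf_profile(
    aligned: Trajectory,
    selection: Selection,
    group_by_residue: bool = True,
) -> RMSFProfile:
    """Root-mean-square fluctuation of selected atoms over an aligned trajectory.

    Atomic RMSF is sqrt(<|r - <r>|^2>) over frames; the per-residue value is
    the mass-weighted mean of the residue's selected atomic RMSF values.
    """
    if aligned.n_frames < 2:
        raise TrajkitError("RMSF requires at least 2 frames")
    if len(selection) == 0:
        raise TrajkitError("empty selection")
    idx = selection.indices
    x = aligned.frames[:, idx, :]
    mean = x.mean(axis=0)
    atomic = np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))
    if not group_by_residue:
        return RMSFProfile(labels=list(idx), values=atomic)
    atoms = aligned.topology.atoms
    masses = aligned.topology.masses()[idx]
    labels: list[tuple[str, int]] = []
    values: list[float] = []
    by_res: dict[tuple[str, int], list[int]] = {}
    for k, ai in enumerate(idx):
        by_res.setdefault(atoms[ai].residue_id, []).append(k)
    for rid, ks in by_res.items():
        w = masses[ks]
        labels.append(rid)
        values.append(float((atomic[ks] * w).sum() / w.sum()))
    return RMSFProfile(labels=labels, values=np.array(values))


def covariance_matrix(aligned: Trajectory, selection: Selection) -> CovarianceMatrix:
    """Mass-weighted, normalized per-residue covariance of motions."""
    if aligned.n_frames < 2:
        raise TrajkitError("covariance requires at least 2 frames")
    if len(selection) == 0:
        raise TrajkitError("empty selection")
    idx = selection.indices
    atoms = aligned.topology.atoms
    masses = aligned.topology.masses()
    by_res: dict[tuple[str, int], list[int]] = {}
    for ai in idx:
        by_res.setdefault(atoms[ai].residue_id, []).append(ai)
    labels = list(by_res)
    n_res = len(labels)
    t = aligned.n_frames
    disp = np.empty((t, n_res, 3))
    for j, rid in enumerate(labels):
        ais = by_res[rid]
        w = masses[ais]
        pos = (aligned.frames[:, ais, :] * w[None, :, None]).sum(1) / w.sum()
        disp[:, j, :] = pos - pos.mean(0)
    # inner products: (n_res, n_res) sum over frames and xyz
    flat = disp.transpose(1, 0, 2).reshape(n_res, -1)
    cov = flat @ flat.T / t
    var = np.diag(cov).copy()
    zero = var <= 1e-300
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} residue(s) with zero variance; their "
            "covariance rows are set to 0 (diagonal 1)",
            stacklevel=2,
        )
        var[zero] = 1.0
    norm = np.sqrt(np.outer(var, var))
    c = cov / norm
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return CovarianceMatrix(labels=labels, values=c)


def correlated_partners(
    cov: CovarianceMatrix, residue, threshold: float = 0.75
) -> list[tuple[tuple[str, int], float]]:
    """Residues whose motion correlates with ``residue`` at |C| >= threshold.

    Returns (residue label, signed correlation) pairs, excluding the query
    residue itself, strongest first.
    """
    rid = tuple(residue)
    if rid not in cov.labels:
        raise TrajkitError(f"residue {rid} not present in covariance matrix")
    i = cov.labels.index(rid)
    out = [
        (cov.labels[j], float(cov.values[i, j]))
        for j in range(len(cov.labels))
        if j != i and abs(cov.values[i, j]) >= threshold
    ]
    return sorted(out, key=lambda p: -abs(p[1]))
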