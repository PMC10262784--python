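"""Solvent-accessible surface area (Shrake-Rupley) and buried surface area.

SASA uses deterministic Fibonacci-lattice quadrature on each atom's solvent
sphere of radius r_vdw + probe (probe 1.4 A, a water molecule); a sphere
point is occluded when it falls inside any neighbouring atom's solvent
sphere. Buried surface area of a two-chain complex follows the standard
convention

    BSA = (SASA(A alone) + SASA(B alone) - SASA(complex)) / 2.

Waters and ions are conventionally excluded from the context (they are
filtered at the PDB-reading stage by default).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._geom import fibonacci_sphere
from .errors import TrajkitError
from .model_io import Selection, Structure, Trajectory

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class SASAResult:
    atom_indices: np.ndarray  # indices into the structure the areas refer to
    per_atom: np.ndarray  # A^2, aligned with atom_indices
    per_residue: dict  # (chain, resid) -> A^2
    total: float
    probe_radius: float
    n_sphere_points: int


def _sasa_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    subset: np.ndarray,
    probe: float,
    n_points: int,
    sphere: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom accessible area for atoms in ``subset``, occluded by all atoms."""
    if sphere is None:
        sphere = fibonacci_sphere(n_points)
    solv = radii + probe
    tree = cKDTree(coords)
    reach = 2.0 * probe + radii.max()
    out = np.empty(subset.size)
    for k, i in enumerate(subset):
        r_i = solv[i]
        neighbors = tree.query_ball_point(coords[i], r_i + reach)
        neighbors = [j for j in neighbors if j != i]
        pts = coords[i] + r_i * sphere
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            keep = nb[np.linalg.norm(coords[nb] - coords[i], axis=1) < r_i + solv[nb]]
            if keep.size:
                d2 = ((pts[:, None, :] - coords[keep][None, :, :]) ** 2).sum(2)
                exposed = np.all(d2 >= (solv[keep] ** 2)[None, :], axis=1)
            else:
                exposed = np.ones(len(pts), dtype=bool)
        else:
            exposed = np.ones(len(pts), dtype=bool)
        out[k] = exposed.mean() * 4.0 * np.pi * r_i**2
    return out


def shrake_rupley_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    subset: Selection | None = None,
) -> SASAResult:
    """Shrake-Rupley SASA of a structure (optionally of a subset of atoms,
    still occluded by the whole structure)."""
    if n_points < 64:
        raise TrajkitError("n_points must be >= 64 for acceptable quadrature")
    radii = structure.vdw_radii()  # raises if unassigned
    idx = (
        np.arange(structure.n_atoms) if subset is None else subset.indices
    )
    if idx.size == 0:
        raise TrajkitError("empty subset")
    per_atom = _sasa_areas(structure.coords, radii, idx, probe, n_points)
    per_res: dict = {}
    for k, i in enumerate(idx):
        rid = structure.atoms[i].residue_id
        per_res[rid] = per_res.get(rid, 0.0) + float(per_atom[k])
    return SASAResult(
        atom_indices=idx,
        per_atom=per_atom,
        per_residue=per_res,
        total=float(per_atom.sum()),
        probe_radius=probe,
        n_sphere_points=n_points,
    )


def sasa_series(
    traj: Trajectory,
    target: Selection,
    context: Selection | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-frame SASA (A^2) of the target atoms within a context.

    Typical use: the Ser65 residue of ubiquitin computed in the context of
    the whole kinase-ubiquitin complex. The target must be a subset of the
    context.
    """
    if len(target) == 0:
        raise TrajkitError("empty target selection")
    ctx = (
        np.arange(traj.n_atoms) if context is None else context.indices
    )
    if not np.isin(target.indices, ctx).all():
        raise TrajkitError("target selection must be a subset of the context")
    radii = traj.topology.vdw_radii()[ctx]
    # target positions within the context-atom subarray
    pos = np.searchsorted(ctx, target.indices)
    sphere = fibonacci_sphere(n_points)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        areas = _sasa_areas(traj.frames[f, ctx], radii, pos, probe, n_points, sphere)
        out[f] = areas.sum()
    return out


@dataclass(frozen=True)
class BSASeries:
    values: np.ndarray  # A^2 per frame, >= 0
    probe_radius: float
    n_sphere_points: int


def buried_surface_area(
    traj: Trajectory,
    chain_a: Selection,
    chain_b: Selection,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> BSASeries:
    """Per-frame buried surface area between two disjoint selections."""
    ia, ib = chain_a.indices, chain_b.indices
    if ia.size == 0 or ib.size == 0:
        raise TrajkitError("both chain selections must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise TrajkitError("chain selections overlap")
    radii = traj.topology.vdw_radii()
    ra, rb = radii[ia], radii[ib]
    iab = np.concatenate([ia, ib])
    rab = radii[iab]
    sphere = fibonacci_sphere(n_points)
    vals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        xa, xb = traj.frames[f, ia], traj.frames[f, ib]
        xab = traj.frames[f, iab]
        sa = _sasa_areas(xa, ra, np.arange(len(ia)), probe, n_points, sphere).sum()
        sb = _sasa_areas(xb, rb, np.arange(len(ib)), probe, n_points, sphere).sum()
        sab = _sasa_areas(xab, rab, np.arange(len(iab)), probe, n_points, sphere).sum()
        vals[f] = (sa + sb - sab) / 2.0
    if np.any(vals < -1e-6):
        warnings.warn(
            f"negative BSA values down to {vals.min():.3g} A^2 clamped to 0",
            stacklevel=2,
        )
    return BSASeries(values=np.clip(vals, 0.0, None), probe_radius=probe,
                     n_sphere_points=n_points)
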