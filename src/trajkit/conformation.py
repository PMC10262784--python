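"""Backbone dihedrals, Ramachandran distributions, distance series and
moving averages.

These are the per-frame conformational metrics used to diagnose the
C-terminal retraction of bound ubiquitin: the (phi, psi) distribution of a
hinge residue compared against reference crystal conformations, the
retraction distance between two landmark residues (Ala46 and Gly76 in
ubiquitin numbering, CA-CA by default) and nanosecond-scale moving
averages of per-frame series.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geom import dihedral, wrap_degrees
from .errors import TrajkitError, UndefinedAngleError
from .model_io import Structure, Trajectory


@dataclass(frozen=True)
class PhiPsi:
    phi: float | None  # None when undefined (chain terminus / missing atoms)
    psi: float | None


def backbone_dihedrals(frame: Structure, chain: str, residue: int) -> PhiPsi:
    """(phi, psi) of one residue in degrees, IUPAC sign convention.

    A terminal residue (or one missing the needed neighbours) gets None for
    the undefined angle rather than a silent NaN. Degenerate (collinear)
    geometry raises :class:`UndefinedAngleError`.
    """
    def coord(res: int, name: str):
        try:
            return frame.coords[frame.find_atom(chain, res, name)]
        except TrajkitError:
            return None

    n = coord(residue, "N")
    ca = coord(residue, "CA")
    c = coord(residue, "C")
    if n is None or ca is None or c is None:
        raise TrajkitError(
            f"residue {chain}:{residue} is missing backbone atoms"
        )
    c_prev = coord(residue - 1, "C")
    n_next = coord(residue + 1, "N")
    phi = dihedral(c_prev, n, ca, c) if c_prev is not None else None
    psi = dihedral(n, ca, c, n_next) if n_next is not None else None
    return PhiPsi(phi=phi, psi=psi)


@dataclass(frozen=True)
class RamaDistribution:
    residue: tuple[str, int]
    angles: np.ndarray  # (T, 2) degrees; NaN rows where undefined
    reference_points: dict  # label -> (phi, psi)
    near_fractions: dict  # label -> fraction of frames within the radius
    near_radius: float  # degrees


def _circular_rama_distance(phi_psi: np.ndarray, ref: tuple[float, float]) -> np.ndarray:
    d_phi = wrap_degrees(phi_psi[:, 0] - ref[0])
    d_psi = wrap_degrees(phi_psi[:, 1] - ref[1])
    return np.sqrt(np.asarray(d_phi) ** 2 + np.asarray(d_psi) ** 2)


def rama_distribution(
    traj: Trajectory,
    chain: str,
    residue: int,
    references: list[tuple[str, Structure]] | None = None,
    near_radius: float = 30.0,
) -> RamaDistribution:
    """Per-frame (phi, psi) of a residue plus reference-conformation anchors.

    For each labelled reference structure the same residue's angles are
    computed and the fraction of trajectory frames within ``near_radius``
    degrees (wrap-aware Euclidean metric on the torus) is reported — the
    quantitative counterpart of "the cloud sits on the reference dot".
    """
    angles = np.full((traj.n_frames, 2), np.nan)
    for f, frame in enumerate(traj.iter_frames()):
        pp = backbone_dihedrals(frame, chain, residue)
        if pp.phi is not None and pp.psi is not None:
            angles[f] = (pp.phi, pp.psi)
    if np.all(np.isnan(angles[:, 0])):
        raise TrajkitError(
            f"residue {chain}:{residue} has no assignable (phi, psi) in any frame"
        )
    refs: dict = {}
    fractions: dict = {}
    ok = ~np.isnan(angles[:, 0])
    for label, ref_structure in references or []:
        try:
            pp = backbone_dihedrals(ref_structure, chain, residue)
        except TrajkitError:
            warnings.warn(
                f"reference {label!r} lacks residue {chain}:{residue}; skipped",
                stacklevel=2,
            )
            continue
        if pp.phi is None or pp.psi is None:
            warnings.warn(
                f"reference {label!r}: angles undefined at {chain}:{residue}; skipped",
                stacklevel=2,
            )
            continue
        refs[label] = (pp.phi, pp.psi)
        dist = _circular_rama_distance(angles[ok], (pp.phi, pp.psi))
        fractions[label] = float((dist <= near_radius).mean())
    return RamaDistribution(
        residue=(chain, residue),
        angles=angles,
        reference_points=refs,
        near_fractions=fractions,
        near_radius=near_radius,
    )


@dataclass(frozen=True)
class DistanceSeries:
    values: np.ndarray  # Angstrom per frame
    atom_a: tuple[str, int, str]
    atom_b: tuple[str, int, str]
    frame_dt: float
    smoothed: np.ndarray | None = field(default=None)
    window_ps: float | None = None


def distance_series(
    traj: Trajectory,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
) -> DistanceSeries:
    """Per-frame Euclidean distance between two named atoms.

    Atoms are (chain, residue, atom_name); the conventional retraction
    metric uses the CA atoms of the two landmark residues.
    """
    ia = traj.topology.find_atom(*atom_a)
    ib = traj.topology.find_atom(*atom_b)
    vals = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
    return DistanceSeries(
        values=vals, atom_a=atom_a, atom_b=atom_b, frame_dt=traj.frame_dt
    )


def moving_average(series: np.ndarray, window: float, frame_dt: float) -> np.ndarray:
    """Centered moving average with a window given in picoseconds.

    The window is converted to w = round(window / frame_dt) frames, forced
    odd (+1) so it is symmetric, and truncated at the series edges; output
    length equals input length and a constant series is returned unchanged.
    """
    x = np.asarray(series, dtype=float)
    if frame_dt <= 0:
        raise TrajkitError("frame_dt must be positive")
    if window < frame_dt:
        raise TrajkitError("window must be at least one frame long")
    w = int(round(window / frame_dt))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return x.copy()
    half = w // 2
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
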