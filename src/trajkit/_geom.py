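"""Small geometry primitives shared across modules.

All angles are in degrees, all lengths in Angstrom.
"""
from __future__ import annotations

import numpy as np

from .errors import UndefinedAngleError

_DEG = np.pi / 180.0


def wrap_degrees(angle):
    """Wrap angle(s) to the interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def angular_difference(a, b):
    """Smallest absolute difference between two angles on the circle."""
    return np.abs(wrap_degrees(np.asarray(a, dtype=float) - b))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 (IUPAC convention), degrees in (-180, 180].

    Raises :class:`UndefinedAngleError` when the construction is degenerate
    (collinear triples make the torsion axis planes vanish).
    """
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    if np.linalg.norm(n0) < 1e-9 or np.linalg.norm(n1) < 1e-9:
        raise UndefinedAngleError("dihedral undefined: collinear atom triple")
    nb1 = np.linalg.norm(b1)
    x = float(np.dot(n0, n1))
    y = float(np.dot(np.cross(n0, n1), b1 / nb1))
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    v0 = np.asarray(p0, float) - np.asarray(p1, float)
    v1 = np.asarray(p2, float) - np.asarray(p1, float)
    c = np.dot(v0, v1) / (np.linalg.norm(v0) * np.linalg.norm(v1))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, bond_angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d bonded to c with |cd| = bond,
    angle(b,c,d) = bond_angle and dihedral(a,b,c,d) = torsion (degrees)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = bond_angle * _DEG
    tor = torsion * _DEG
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = angle_deg * _DEG
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
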