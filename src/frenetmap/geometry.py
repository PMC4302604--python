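"""Low-level vector geometry: unit vectors, bond/dihedral angles, internal-coordinate
atom placement (NeRF) and rigid transforms.

All angles are radians unless a ``_deg`` suffix says otherwise; coordinates are
ångström 3-vectors (plain ``numpy`` arrays).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "unit",
    "bond_angle",
    "bond_angle_deg",
    "dihedral_angle",
    "place_internal",
    "random_rotation",
    "rigid_transform",
]

_EPS = 1e-12


def unit(v: np.ndarray) -> np.ndarray:
    """Return v / |v|; raises on (near-)zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < _EPS:
        raise ValueError("cannot normalise a zero-length vector")
    return v / n


def bond_angle(a, b, c) -> float:
    """Angle at vertex ``b`` of the triangle a-b-c, in radians, in [0, pi]."""
    u = unit(np.asarray(a, float) - b)
    w = unit(np.asarray(c, float) - b)
    return float(np.arccos(np.clip(u @ w, -1.0, 1.0)))


def bond_angle_deg(a, b, c) -> float:
    return float(np.degrees(bond_angle(a, b, c)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral about the p2-p3 axis, radians in (-pi, pi].

    IUPAC convention: 0 for the eclipsed (cis) arrangement of p1 and p4, pi for
    anti (trans); positive sign for clockwise rotation of the far bond viewed
    from p2 towards p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    v1, v2, v3 = p2 - p1, p3 - p2, p4 - p3
    b1 = np.cross(v1, v2)
    b2 = np.cross(v2, v3)
    n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
    if n1 < _EPS or n2 < _EPS:
        raise ValueError("degenerate (collinear) geometry: dihedral undefined")
    u2 = v2 / np.linalg.norm(v2)
    x = float(b1 @ b2)
    y = float(np.cross(b1, b2) @ u2)
    ang = float(np.arctan2(y, x))
    if ang <= -np.pi:  # pin -pi to +pi so the range is (-pi, pi]
        ang = np.pi
    return ang


def place_internal(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to the chain a-b-c.

    ``bond`` = |d-c|, ``angle_deg`` = angle b-c-d, ``dihedral_deg`` =
    dihedral a-b-c-d (sign convention of :func:`dihedral_angle`).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    # local displacement in the (bc, m, n) frame
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (det = +1)."""
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def rigid_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply x -> R x + t row-wise; rejects improper rotations."""
    rotation = np.asarray(rotation, float)
    if not np.isclose(np.linalg.det(rotation), 1.0, atol=1e-9):
        raise ValueError("rotation must be proper (det = +1)")
    return np.asarray(coords, float) @ rotation.T + np.asarray(translation, float)
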