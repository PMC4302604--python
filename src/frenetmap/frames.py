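"""Discrete Frenet frames on the C-alpha trace and the side-chain framings.

The backbone frame at residue i is the right-handed orthonormal triad

    t_i = (r_{i+1} - r_i) / |r_{i+1} - r_i|
    b_i = (t_{i-1} x t_i) / |t_{i-1} x t_i|
    n_i = b_i x t_i

built purely from three consecutive C-alpha positions.  The virtual backbone
bond and torsion angles follow from consecutive frames:

    cos kappa_{i+1} = t_{i+1} . t_i          kappa in [0, pi]
    cos |tau_{i+1}| = b_{i+1} . b_i          tau in (-pi, pi]

with the sign of tau fixed so that the longitude increases counter-clockwise
about t (sign of (b_i x b_{i+1}) . t_i).  Any atom is mapped onto the
frame-centered unit sphere as a (latitude, longitude) pair, latitude 0 at the
tip of t and longitude 0 on the half-plane of n.

Side chains use the chi1 framing (t along CA->CB, longitude = the standard
chi1 dihedral), the chi2 framing (t along CB->CG, normal from t x t_a with
t_a the backbone tangent), and the generic Z-X framing for the higher levels,
where X is the observer's atom and Z the previously visited one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .geometry import dihedral_angle, unit
from .structure_io import ChainModel, ResidueRecord

__all__ = [
    "FrenetFrame",
    "SideChainFrame",
    "SphericalDirection",
    "BackboneAngles",
    "build_frenet_frames",
    "backbone_kappa_tau",
    "direction_in_frame",
    "chi1_frame",
    "zx_frame",
    "dihedral_frame",
    "build_side_chain_frame",
    "chain_frenet_frames",
    "ramachandran",
    "dihedral_angle",
]

_COLLINEAR_TOL = 1e-7


@dataclass(frozen=True)
class SphericalDirection:
    """Direction on a frame-centered unit sphere.

    latitude in [0, pi] (0 at the tip of t); longitude in (-pi, pi] (0 on the
    n half-plane, increasing counter-clockwise about t).  At the poles the
    longitude is reported as 0 by convention.
    """

    latitude: float
    longitude: float

    def __post_init__(self):
        if not 0.0 <= self.latitude <= math.pi:
            raise ValueError(f"latitude {self.latitude} outside [0, pi]")
        lon = self.longitude
        if lon <= -math.pi:
            lon += 2 * math.pi
        if self.latitude < 1e-12 or math.pi - self.latitude < 1e-12:
            lon = 0.0
        object.__setattr__(self, "longitude", lon)

    @property
    def latitude_deg(self) -> float:
        return math.degrees(self.latitude)

    @property
    def longitude_deg(self) -> float:
        return math.degrees(self.longitude)

    def as_vector(self) -> np.ndarray:
        """Components on the local (t, n, b) axes."""
        sk = math.sin(self.latitude)
        return np.array(
            [
                math.cos(self.latitude),
                sk * math.cos(self.longitude),
                sk * math.sin(self.longitude),
            ]
        )


@dataclass
class FrenetFrame:
    origin: np.ndarray
    t: np.ndarray
    n: np.ndarray
    b: np.ndarray
    index: int = -1
    flagged: bool = False  # collinear-tangent fallback applied

    def axes(self) -> np.ndarray:
        return np.stack([self.t, self.n, self.b])


@dataclass
class SideChainFrame(FrenetFrame):
    level: str = "chi1"
    t_a: np.ndarray | None = None


@dataclass
class BackboneAngles:
    """Per-residue virtual bond (kappa) and torsion (tau) angles, radians.

    Arrays are chain-length; NaN where undefined (termini, breaks, collinear
    fallbacks).  kappa[i] and tau[i] carry the angles between frames i-1 and i.
    """

    kappa: np.ndarray
    tau: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def _orthonormal_frame(origin, t, b, index, flagged=False) -> FrenetFrame:
    n = np.cross(b, t)
    return FrenetFrame(origin=origin, t=t, n=unit(n), b=b, index=index, flagged=flagged)


def _any_perpendicular(t: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return unit(np.cross(t, ref))


def build_frenet_frames(ca_trace: np.ndarray) -> list[FrenetFrame | None]:
    """Discrete Frenet frames of an ordered C-alpha trace.

    Returns a list aligned with the trace; entries are None at the first and
    last positions (where t_{i-1} or t_i does not exist).  Near-collinear
    consecutive tangents fall back to the nearest preceding defined binormal
    (discrete parallel transport) and the frame is flagged.
    """
    ca = np.asarray(ca_trace, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or ca.shape[0] < 3:
        raise ValueError("trace too short: need at least 3 points of shape (N, 3)")
    diffs = np.diff(ca, axis=0)
    norms = np.linalg.norm(diffs, axis=1)
    if np.any(norms < 1e-9):
        raise ValueError("coincident consecutive points in trace")
    tangents = diffs / norms[:, None]  # tangents[i] = t_{i} for i = 0..N-2

    frames: list[FrenetFrame | None] = [None] * len(ca)
    last_b: np.ndarray | None = None
    for i in range(1, len(ca) - 1):
        t_prev, t_i = tangents[i - 1], tangents[i]
        cross = np.cross(t_prev, t_i)
        cn = np.linalg.norm(cross)
        if cn < _COLLINEAR_TOL:
            b = last_b if last_b is not None else _any_perpendicular(t_i)
            # keep b orthogonal to the current tangent
            b = unit(b - t_i * (b @ t_i))
            frames[i] = _orthonormal_frame(ca[i], t_i, b, i, flagged=True)
        else:
            b = cross / cn
            frames[i] = _orthonormal_frame(ca[i], t_i, b, i)
        last_b = frames[i].b
    return frames


def backbone_kappa_tau(frames: list[FrenetFrame | None]) -> BackboneAngles:
    """Virtual bond and torsion angles from consecutive Frenet frames."""
    n = len(frames)
    if sum(f is not None for f in frames) < 2:
        raise ValueError("need at least 2 consecutive frames")
    kappa = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    for i in range(1, n):
        f0, f1 = frames[i - 1], frames[i]
        if f0 is None or f1 is None:
            continue
        kappa[i] = math.acos(float(np.clip(f0.t @ f1.t, -1.0, 1.0)))
        flagged[i] = f0.flagged or f1.flagged
        if flagged[i]:
            continue  # binormal is a transported copy: tau undefined
        mag = math.acos(float(np.clip(f0.b @ f1.b, -1.0, 1.0)))
        sign = float(np.cross(f0.b, f1.b) @ f0.t)
        tau[i] = math.copysign(mag, sign) if sign != 0.0 else mag
    return BackboneAngles(kappa=kappa, tau=tau, flagged=flagged)


def direction_in_frame(
    frame: FrenetFrame,
    point: np.ndarray,
    translate_to: np.ndarray | None = None,
) -> SphericalDirection:
    """Latitude/longitude of a point on the frame-centered unit sphere.

    With ``translate_to`` the frame axes stay fixed and only the origin moves
    (the roller-coasting observer of the backbone C-alpha map).
    """
    origin = frame.origin if translate_to is None else np.asarray(translate_to, float)
    v = np.asarray(point, float) - origin
    r = np.linalg.norm(v)
    if r < 1e-12:
        raise ValueError("zero-length direction: point coincides with frame origin")
    u = v / r
    lat = math.acos(float(np.clip(u @ frame.t, -1.0, 1.0)))
    lon = math.atan2(float(u @ frame.b), float(u @ frame.n))
    return SphericalDirection(latitude=lat, longitude=lon)


# -- side-chain framings ------------------------------------------------------


def chi1_frame(r_n: np.ndarray, r_ca: np.ndarray, r_cb: np.ndarray) -> SideChainFrame:
    """chi1 framing: t along CA->CB, longitude equal to the standard chi1 dihedral.

    The reference vector is the N-atom direction projected perpendicular to t.
    """
    t = unit(np.asarray(r_cb, float) - r_ca)
    s = np.asarray(r_n, float) - r_ca
    perp = s - t * (s @ t)
    if np.linalg.norm(perp) < _COLLINEAR_TOL:
        raise ValueError("N collinear with CA-CB axis: chi1 frame undefined")
    n = unit(perp)
    b = np.cross(t, n)
    return SideChainFrame(origin=np.asarray(r_ca, float), t=t, n=n, b=b, level="chi1")


def zx_frame(
    r_z: np.ndarray,
    r_x: np.ndarray,
    t_a: np.ndarray,
    origin: str = "distal",
    level: str = "zx",
) -> SideChainFrame | None:
    """Generic observer frame at atom X reached from atom Z.

    t points Z->X; n is along t x t_a with t_a the backbone Frenet tangent of
    the residue; b = t x n.  Returns None (degenerate) when t is parallel to
    t_a.  ``origin`` selects the distal (X) or proximal (Z) sphere center.
    """
    t = unit(np.asarray(r_x, float) - r_z)
    cross = np.cross(t, np.asarray(t_a, float))
    if np.linalg.norm(cross) < _COLLINEAR_TOL:
        return None
    n = unit(cross)
    b = np.cross(t, n)
    o = np.asarray(r_x if origin == "distal" else r_z, float)
    return SideChainFrame(origin=o, t=t, n=n, b=b, level=level, t_a=np.asarray(t_a, float))


def dihedral_frame(r_ref: np.ndarray, r_z: np.ndarray, r_x: np.ndarray) -> SideChainFrame:
    """Frame whose longitude reproduces the dihedral ref-Z-X-Y for any atom Y.

    t points Z->X and the reference direction is ref's direction from Z
    projected perpendicular to t; for (N, CA, CB) this is exactly the chi1
    framing.
    """
    return chi1_frame(r_ref, r_z, r_x)


def build_side_chain_frame(
    residue: ResidueRecord,
    level: str,
    backbone_tangent: np.ndarray | None = None,
    origin: str = "distal",
) -> SideChainFrame | None:
    """Frame used to observe the atoms of ``level`` (gamma..eta) of a residue.

    chi1: needs N, CA, CB.  All higher levels use the Z-X framing anchored on
    the residue's observation path (Z, X = the two path atoms below the
    level), which needs the backbone tangent t_a.  Returns None when atoms are
    missing or the construction is degenerate.
    """
    if level == "chi1":
        pts = [residue.coord(a) for a in ("N", "CA", "CB")]
        if any(p is None for p in pts):
            return None
        return chi1_frame(*pts)
    if level == "chi2":
        level = "delta"  # Z=CB, X=CG framing observing the delta level
    if level not in chemistry.LEVELS or level == "beta":
        raise ValueError(f"no side-chain frame for level {level!r}")
    if backbone_tangent is None:
        raise ValueError("backbone_tangent (t_a) required for Z-X framings")
    i = chemistry.LEVEL_INDEX[level]
    path = ("CA",) + chemistry.SIDE_CHAIN_PATH.get(residue.resname, ())
    if i >= len(path):
        return None
    z_name, x_name = path[i - 1], path[i]
    r_z, r_x = residue.coord(z_name), residue.coord(x_name)
    if r_z is None or r_x is None:
        return None
    return zx_frame(r_z, r_x, backbone_tangent, origin=origin, level=level)


# -- chain-level helpers ------------------------------------------------------


def chain_frenet_frames(chain: ChainModel) -> list[FrenetFrame | None]:
    """Frenet frames for every residue of a chain; None at termini, breaks and
    missing C-alphas.  No frame spans a recorded break."""
    frames: list[FrenetFrame | None] = [None] * len(chain.residues)
    for start, stop in chain.segments():
        if stop - start < 3:
            continue
        ca = np.array([chain.residues[i].coord("CA") for i in range(start, stop)])
        seg_frames = build_frenet_frames(ca)
        for k, f in enumerate(seg_frames):
            if f is not None:
                f.index = start + k
                frames[start + k] = f
    return frames


def chain_kappa_tau(chain: ChainModel) -> BackboneAngles:
    """kappa/tau along a chain, NaN across breaks and termini."""
    n = len(chain.residues)
    kappa = np.full(n, np.nan)
    tau = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    for start, stop in chain.segments():
        if stop - start < 4:
            continue
        ca = np.array([chain.residues[i].coord("CA") for i in range(start, stop)])
        ang = backbone_kappa_tau(build_frenet_frames(ca))
        kappa[start:stop] = ang.kappa
        tau[start:stop] = ang.tau
        flagged[start:stop] = ang.flagged
    return BackboneAngles(kappa=kappa, tau=tau, flagged=flagged)


def ramachandran(chain: ChainModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi) in radians; NaN at termini, breaks and where
    backbone atoms are missing."""
    n = len(chain.residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    cuts = set(chain.breaks)
    for i, r in enumerate(chain.residues):
        n_i, ca_i, c_i = r.coord("N"), r.coord("CA"), r.coord("C")
        if any(p is None for p in (n_i, ca_i, c_i)):
            continue
        if i > 0 and (i - 1) not in cuts:
            c_prev = chain.residues[i - 1].coord("C")
            if c_prev is not None:
                try:
                    phi[i] = dihedral_angle(c_prev, n_i, ca_i, c_i)
                except ValueError:
                    pass
        if i < n - 1 and i not in cuts:
            n_next = chain.residues[i + 1].coord("N")
            if n_next is not None:
                try:
                    psi[i] = dihedral_angle(n_i, ca_i, c_i, n_next)
                except ValueError:
                    pass
    return phi, psi


def chi_dihedral(residue: ResidueRecord, which: int = 1) -> float | None:
    """Standard chi1 (N-CA-CB-G) or chi2 (CA-CB-G-D) dihedral in radians."""
    path = chemistry.SIDE_CHAIN_PATH.get(residue.resname, ())
    if which == 1:
        names = ("N", "CA", "CB") + ((path[1],) if len(path) > 1 else ())
    elif which == 2:
        names = ("CA", "CB") + (tuple(path[1:3]) if len(path) > 2 else ())
    else:
        raise ValueError("which must be 1 or 2")
    if len(names) < 4:
        return None
    pts = [residue.coord(a) for a in names]
    if any(p is None for p in pts):
        return None
    try:
        return dihedral_angle(*pts)
    except ValueError:
        return None
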