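"""Ideal and perturbed synthetic protein geometry.

Generates C-alpha traces with prescribed virtual-bond geometry (helices,
planar zigzag strands), full ideal-geometry heavy-atom backbones on top of a
trace, and internal-coordinate backbones from (phi, psi, omega) dihedrals, so
every frame/map/reconstruction operation is testable without any structure
download.

The trace-based backbone builder places each peptide unit as a rigid planar
group bridging consecutive C-alpha atoms with the omega dihedral exactly 180
degrees (or exactly 0 for requested cis bonds).  The rotational freedom of
each plane about its C-alpha virtual bond is fixed by requiring the
N-CA-C tetrahedral angle at each interior C-alpha to equal the configured
value exactly; C-beta is then solved in closed form from the two remaining
tetrahedral angles with the L-amino-acid chirality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .geometry import dihedral_angle, place_internal, random_rotation, rigid_transform, unit
from .structure_io import (
    AtomRecord,
    ChainModel,
    ResidueRecord,
    _annotate_isomers,
    _detect_breaks,
)

__all__ = [
    "HelixParams",
    "StrandParams",
    "IdealGeometry",
    "generate_trace",
    "generate_ideal_backbone",
    "backbone_from_dihedrals",
    "apply_rigid_transform",
    "reflect_coords",
]


@dataclass(frozen=True)
class HelixParams:
    """Ideal alpha-helical C-alpha trace: ~3.8 A virtual bonds whose (kappa,
    tau) sit in the alpha region of the backbone map."""

    n_residues: int = 20
    # defaults are the C-alpha helix of an ideal-geometry backbone at
    # (phi, psi) = (-57, -47): virtual bond 3.804 A, (kappa, tau) ~ (1.55, 0.89)
    rise: float = 1.5353  # A per residue along the axis
    twist: float = 99.768  # degrees per residue; sign flips with handedness
    radius: float = 2.2755  # A
    handedness: int = 1  # +1 right-handed, -1 left-handed
    seed: int = 0


@dataclass(frozen=True)
class StrandParams:
    """Planar zigzag strand trace with a prescribed virtual bond and kappa."""

    n_residues: int = 20
    bond_length: float = 3.8  # A
    kappa: float = 1.0  # radians; turning angle at each C-alpha
    seed: int = 0


@dataclass(frozen=True)
class IdealGeometry:
    """Bond lengths (A) and angles (degrees) for backbone heavy-atom placement."""

    n_ca: float
    ca_c: float
    c_o: float
    c_n: float
    ca_cb: float
    cb_cg: float
    cg_cd: float
    theta_NC: float
    theta_Nbeta: float
    theta_betaC: float
    ang_ca_c_n: float
    ang_c_n_ca: float
    ang_ca_c_o: float
    ang_ca_cb_cg: float
    ang_cb_cg_cd: float

    @classmethod
    def default(cls) -> "IdealGeometry":
        cfg = json.loads(
            resources.files("frenetmap").joinpath("data/ideal_geometry.json").read_text()
        )
        b, a = cfg["bond_lengths"], cfg["angles"]
        return cls(
            n_ca=b["N-CA"], ca_c=b["CA-C"], c_o=b["C-O"], c_n=b["C-N"],
            ca_cb=b["CA-CB"], cb_cg=b["CB-CG"], cg_cd=b["CG-CD"],
            theta_NC=a["theta_NC"], theta_Nbeta=a["theta_Nbeta"],
            theta_betaC=a["theta_betaC"], ang_ca_c_n=a["CA-C-N"],
            ang_c_n_ca=a["C-N-CA"], ang_ca_c_o=a["CA-C-O"],
            ang_ca_cb_cg=a["CA-CB-CG"], ang_cb_cg_cd=a["CB-CG-CD"],
        )

    def with_angles(self, **kw) -> "IdealGeometry":
        return replace(self, **kw)


def generate_trace(params: HelixParams | StrandParams) -> np.ndarray:
    """Deterministic C-alpha trace from helix or strand parameters."""
    n = params.n_residues
    if n < 3:
        raise ValueError("need at least 3 residues")
    if isinstance(params, HelixParams):
        if params.rise <= 0 or params.radius <= 0:
            raise ValueError("rise and radius must be positive")
        omega = math.radians(params.twist) * (1 if params.handedness >= 0 else -1)
        i = np.arange(n)
        return np.column_stack(
            [
                params.radius * np.cos(omega * i),
                params.radius * np.sin(omega * i),
                params.rise * i,
            ]
        )
    if isinstance(params, StrandParams):
        L, kappa = params.bond_length, params.kappa
        if L <= 0 or not 0 <= kappa < math.pi:
            raise ValueError("invalid strand parameters")
        # planar zigzag p_i = (i dx, (-1)^i h, 0); kappa is the turning angle
        c = math.cos(kappa)
        dx = L * math.sqrt((1 + c) / 2.0)
        h = 0.5 * L * math.sqrt(max(0.0, (1 - c) / 2.0)) * 2.0 / 2.0
        # |diff| = sqrt(dx^2 + 4 h^2) = L  and  cos kappa = (dx^2 - 4 h^2)/L^2
        h = 0.5 * math.sqrt(max(0.0, L * L - dx * dx))
        i = np.arange(n)
        return np.column_stack([i * dx, np.where(i % 2 == 0, h, -h), np.zeros(n)])
    raise TypeError(f"unsupported trace parameters {type(params)!r}")


# -- rigid transforms ---------------------------------------------------------


def apply_rigid_transform(
    coords: np.ndarray,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Proper rigid motion of a coordinate set (random when seed is given)."""
    if rotation is None or translation is None:
        rng = np.random.default_rng(seed)
        if rotation is None:
            rotation = random_rotation(rng)
        if translation is None:
            translation = rng.normal(scale=10.0, size=3)
    return rigid_transform(coords, rotation, translation)


def reflect_coords(coords: np.ndarray) -> np.ndarray:
    """Mirror through the xy-plane (for chirality tests only)."""
    out = np.asarray(coords, float).copy()
    out[..., 2] *= -1.0
    return out


# -- trace-based ideal backbone ----------------------------------------------

_CHIRALITY_SIGN = 1.0  # (u_N x u_C) . u_CB > 0 realises the L-configuration


def _solve_peptide_plane_2d(d: float, geom: IdealGeometry, cis: bool):
    """In-plane positions of C and N bridging two C-alpha atoms a distance d
    apart, with ideal CA-C, C-N, N-CA lengths, the ideal CA-C-N angle and an
    omega dihedral of exactly 180 (trans) or 0 (cis) degrees.

    Returns (alpha, s): the CA->C elevation angle off the virtual bond and the
    in-plane side sign of N relative to the CA-C ray.  The residual closure
    mismatch is absorbed by the C-N-CA angle.
    """
    key = (round(d, 9), round(geom.ca_c, 6), round(geom.c_n, 6), round(geom.n_ca, 6),
           round(geom.ang_ca_c_n, 6), cis)
    if key in _PLANE_CACHE:
        return _PLANE_CACHE[key]
    th = math.radians(geom.ang_ca_c_n)

    def n_pos(alpha: float, s: float) -> np.ndarray:
        C = geom.ca_c * np.array([math.cos(alpha), math.sin(alpha)])
        u = unit(-C)  # C -> CA(i)
        # rotate u by +/- theta in-plane
        rot = np.array(
            [[math.cos(s * th), -math.sin(s * th)], [math.sin(s * th), math.cos(s * th)]]
        )
        return C + geom.c_n * (rot @ u)

    def closure(alpha: float, s: float) -> float:
        N = n_pos(alpha, s)
        return float(np.hypot(N[0] - d, N[1])) - geom.n_ca

    target_omega = 0.0 if cis else 180.0
    solutions = []
    for s in (+1.0, -1.0):
        grid = np.linspace(1e-3, math.pi - 1e-3, 360)
        vals = [closure(a, s) for a in grid]
        for k in range(len(grid) - 1):
            if vals[k] == 0.0 or vals[k] * vals[k + 1] < 0:
                alpha = brentq(lambda a: closure(a, s), grid[k], grid[k + 1], xtol=1e-14)
                C = geom.ca_c * np.array([math.cos(alpha), math.sin(alpha)])
                N = n_pos(alpha, s)
                A3 = np.array([0.0, 0.0, 0.0])
                B3 = np.array([d, 0.0, 0.0])
                C3 = np.array([C[0], C[1], 0.0])
                N3 = np.array([N[0], N[1], 0.0])
                try:
                    omega = math.degrees(dihedral_angle(A3, C3, N3, B3))
                except ValueError:
                    continue
                if abs(abs(omega) - target_omega) > 1.0:
                    continue
                # closure leaves the C-N-CA angle free; prefer the root
                # closest to its ideal value
                cnca = math.degrees(
                    math.acos(
                        float(np.clip(unit(C - N) @ unit(np.array([d, 0.0]) - N), -1, 1))
                    )
                )
                solutions.append((abs(cnca - geom.ang_c_n_ca), alpha, s))
    if not solutions:
        raise ValueError(
            f"no {'cis' if cis else 'trans'} peptide-plane closure for CA-CA "
            f"distance {d:.3f} A (typical trans ~3.8, cis ~2.9)"
        )
    solutions.sort()
    _PLANE_CACHE[key] = (solutions[0][1], solutions[0][2])
    return _PLANE_CACHE[key]


_PLANE_CACHE: dict = {}


def _plane_atoms(A, B, e2, alpha, s, geom: IdealGeometry):
    """3D C and N of the peptide plane spanned by e1 = unit(B-A) and e2."""
    e1 = unit(B - A)
    th = math.radians(geom.ang_ca_c_n)
    C = A + geom.ca_c * (math.cos(alpha) * e1 + math.sin(alpha) * e2)
    u = unit(A - C)
    # rotate u by s*theta within the (e1, e2) plane
    normal = np.cross(e1, e2)
    u_perp = np.cross(normal, u)
    u_cn = math.cos(s * th) * u + math.sin(s * th) * u_perp
    N = C + geom.c_n * u_cn
    return C, N


def _solve_cb(ca, u_n, u_c, geom: IdealGeometry) -> np.ndarray:
    """Exact C-beta direction from the two side-chain tetrahedral angles,
    with L chirality: (u_N x u_C) . u_CB > 0."""
    c = float(u_n @ u_c)
    t1, t2 = math.cos(math.radians(geom.theta_Nbeta)), math.cos(math.radians(geom.theta_betaC))
    det = 1.0 - c * c
    if det < 1e-12:
        raise ValueError("degenerate N/C directions; cannot place CB")
    x = (t1 - c * t2) / det
    y = (t2 - c * t1) / det
    nrm2 = x * x + y * y + 2 * x * y * c
    if nrm2 > 1.0:
        raise ValueError("tetrahedral angles incompatible; no real CB direction")
    z = math.sqrt(1.0 - nrm2)
    w = unit(np.cross(u_n, u_c))
    u_cb = x * u_n + y * u_c + _CHIRALITY_SIGN * z * w
    return ca + geom.ca_cb * u_cb


def generate_ideal_backbone(
    trace: np.ndarray,
    geometry: IdealGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    resnames: list[str] | str = "ALA",
    cis_bonds: tuple[int, ...] = (),
    chi1_deg: float | np.ndarray | None = None,
    chi2_deg: float | np.ndarray | None = None,
    ss_label: str = "loop",
) -> ChainModel:
    """Full heavy-atom backbone (N, CA, C, O, CB) on a C-alpha trace.

    Peptide bonds are exactly trans (omega = 180 deg) except at the 0-based
    bond indices in ``cis_bonds`` (omega = 0; these need short ~2.9 A virtual
    bonds in the trace).  With ``noise_sd = 0`` the three tetrahedral angles
    at every C-alpha equal the configured values exactly.  ``chi1_deg`` (and
    ``chi2_deg``) optionally add the gamma (and delta) path atoms at the given
    side-chain dihedrals.  Gaussian coordinate noise is applied to every atom
    when ``noise_sd > 0``.
    """
    geom = geometry or IdealGeometry.default()
    ca = np.asarray(trace, float)
    n = len(ca)
    if n < 2:
        raise ValueError("trace too short")
    if isinstance(resnames, str):
        resnames = [resnames] * n
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    chi1 = _broadcast_chi(chi1_deg, n)
    chi2 = _broadcast_chi(chi2_deg, n)

    planes_C, planes_N = _propagate_planes(ca, geom, cis_bonds)
    theta_nc = math.radians(geom.theta_NC)

    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n):
        res = ResidueRecord(resname=resnames[i], seqnum=i + 1, ss_label=ss_label)
        atoms = {"CA": ca[i]}
        # N: from plane i-1, or synthesised at the N terminus
        if i > 0:
            atoms["N"] = planes_N[i - 1]
        # C: from plane i, or synthesised at the C terminus
        if i < n - 1:
            atoms["C"] = planes_C[i]
        if i == 0 and n >= 2:
            atoms["N"] = _terminal_partner(ca[0], atoms["C"], planes_C[0], planes_N[0],
                                           geom.n_ca, theta_nc, ca[1])
        if i == n - 1 and n >= 2:
            atoms["C"] = _terminal_partner(ca[-1], atoms["N"], planes_C[-2], planes_N[-2],
                                           geom.ca_c, theta_nc, ca[-2])
        # O sits in the peptide plane after CA_i, anti-bisecting CA and next N
        if i < n - 1:
            u1 = unit(ca[i] - atoms["C"])
            u2 = unit(planes_N[i] - atoms["C"])
            atoms["O"] = atoms["C"] + geom.c_o * unit(-(u1 + u2))
        if resnames[i] != "GLY" and "N" in atoms and "C" in atoms:
            u_n = unit(atoms["N"] - ca[i])
            u_c = unit(atoms["C"] - ca[i])
            atoms["CB"] = _solve_cb(ca[i], u_n, u_c, geom)
            if chi1[i] is not None and "CB" in atoms:
                from .chemistry import SIDE_CHAIN_PATH

                path = SIDE_CHAIN_PATH.get(resnames[i], ())
                if len(path) > 1:
                    atoms[path[1]] = place_internal(
                        atoms["N"], ca[i], atoms["CB"],
                        geom.cb_cg, geom.ang_ca_cb_cg, chi1[i],
                    )
                    if chi2[i] is not None and len(path) > 2:
                        atoms[path[2]] = place_internal(
                            ca[i], atoms["CB"], atoms[path[1]],
                            geom.cg_cd, geom.ang_cb_cg_cd, chi2[i],
                        )
        for name, coord in atoms.items():
            coord = np.asarray(coord, float)
            if noise_sd > 0:
                coord = coord + rng.normal(scale=noise_sd, size=3)
            res.atoms.append(AtomRecord(name=name, element=_elem(name), coord=coord))
        residues.append(res)

    chain = ChainModel(pdb_id="SYNT", chain_id="A", residues=residues)
    _detect_breaks(chain)
    _annotate_isomers(chain)
    return chain


_BRANCH_SIGN = +1.0  # peptide-plane branch giving protein-like phi/psi on
#                      right-handed traces (the two branches are related by a
#                      plane flip; either satisfies omega and theta_NC exactly)


def _propagate_planes(ca: np.ndarray, geom: IdealGeometry, cis_bonds=()):
    """Orient every peptide plane along a trace.

    The first plane's rotation about its virtual bond is a free parameter;
    each later plane is then fixed (up to the global branch convention) by
    requiring the exact theta_NC angle at the shared C-alpha.  The first
    rotation is chosen deterministically as the grid candidate that lets the
    whole chain propagate with the largest worst-case closure margin.
    """
    n = len(ca)
    theta_nc = math.radians(geom.theta_NC)
    c_target = math.cos(theta_nc)
    solved2d = [
        _solve_peptide_plane_2d(float(np.linalg.norm(ca[k + 1] - ca[k])), geom,
                                cis=(k in cis_bonds))
        for k in range(n - 1)
    ]

    def run(phi_first: float, branch_sign: float):
        planes_C = [None] * (n - 1)
        planes_N = [None] * (n - 1)
        margin = math.inf
        prev_u_n = None
        for k in range(n - 1):
            A, B = ca[k], ca[k + 1]
            alpha, s = solved2d[k]
            e1 = unit(B - A)
            p = _perp(e1)
            q = np.cross(e1, p)
            if prev_u_n is None:
                phi = phi_first
            else:
                K = math.cos(alpha) * float(prev_u_n @ e1)
                a_c = math.sin(alpha) * float(prev_u_n @ p)
                b_c = math.sin(alpha) * float(prev_u_n @ q)
                R = math.hypot(a_c, b_c)
                m = R - abs(c_target - K)
                margin = min(margin, m)
                if R < 1e-12 or m < 0:
                    return None, margin, 0.0
                delta = math.acos(max(-1.0, min(1.0, (c_target - K) / R)))
                phi = math.atan2(b_c, a_c) + branch_sign * delta
            e2 = math.cos(phi) * p + math.sin(phi) * q
            C, N = _plane_atoms(A, B, e2, alpha, s, geom)
            planes_C[k], planes_N[k] = C, N
            prev_u_n = unit(N - B)
        # interior phi dihedrals C_{i-1} - N_i - CA_i - C_i; the L-backbone
        # convention prefers negative phi
        phis = []
        for i in range(1, n - 1):
            try:
                phis.append(
                    dihedral_angle(planes_C[i - 1], planes_N[i - 1], ca[i], planes_C[i])
                )
            except ValueError:
                pass
        mean_phi = float(np.mean(phis)) if phis else 0.0
        return (planes_C, planes_N), margin, mean_phi

    if n == 2:
        planes, _, _ = run(0.0, +1.0)
        return planes
    best = None  # (not-L penalty, -margin, branch order, grid index) ascending
    best_planes = None
    for bi, sign in enumerate((+1.0, -1.0)):
        for gi, phi in enumerate(np.linspace(0.0, 2 * math.pi, 72, endpoint=False)):
            planes, margin, mean_phi = run(float(phi), sign)
            if planes is None:
                continue
            key = (0 if mean_phi < 0 else 1, -margin, bi, gi)
            if best is None or key < best:
                best, best_planes = key, planes
    if best_planes is None:
        raise ValueError(
            f"cannot realise theta_NC={geom.theta_NC} deg on this trace: "
            "no peptide-plane orientation propagates through the chain"
        )
    return best_planes


def _broadcast_chi(chi, n):
    if chi is None:
        return [None] * n
    arr = np.broadcast_to(np.asarray(chi, float), (n,))
    return list(arr)


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))


def _initial_plane_rotation(ca: np.ndarray, k: int) -> float:
    """Deterministic first-plane orientation: align e2 with the (negated)
    local curvature direction when available."""
    if len(ca) >= 3:
        e1 = unit(ca[k + 1] - ca[k])
        curve = ca[k + 2] - ca[k + 1] if k + 2 < len(ca) else ca[k] - ca[k + 1]
        w = curve - e1 * (curve @ e1)
        if np.linalg.norm(w) > 1e-9:
            p = _perp(e1)
            q = np.cross(e1, p)
            w = unit(w)
            return math.atan2(float(w @ q), float(w @ p)) + math.pi
    return 0.0


def _terminal_partner(ca, known, plane_c, plane_n, bond, theta_nc, other_ca):
    """Place the missing terminal N (or C) by rotating the known partner
    direction by theta_NC about the terminal peptide-plane normal."""
    u_known = unit(known - ca)
    normal = np.cross(plane_c - plane_n, other_ca - ca)
    # rotation axis must be exactly perpendicular to u_known for the rotated
    # candidate to make the exact theta_NC angle with it
    axis = normal - u_known * float(normal @ u_known)
    if np.linalg.norm(axis) < 1e-9:
        axis = _perp(u_known)
    axis = unit(axis)
    c, s = math.cos(theta_nc), math.sin(theta_nc)
    u_perp = np.cross(axis, u_known)
    cand1 = c * u_known + s * u_perp
    cand2 = c * u_known - s * u_perp
    # keep the candidate pointing away from the chain interior
    away = unit(ca - other_ca)
    u = cand1 if float(cand1 @ away) >= float(cand2 @ away) else cand2
    return ca + bond * u


def _elem(name: str) -> str:
    return {"N": "N", "O": "O", "S": "S"}.get(name[0], "C")


# -- internal-coordinate backbone builder -------------------------------------


def backbone_from_dihedrals(
    phi_deg,
    psi_deg,
    omega_deg=180.0,
    geometry: IdealGeometry | None = None,
    resnames: list[str] | str = "ALA",
) -> ChainModel:
    """Backbone built atom-by-atom from (phi, psi, omega) internal coordinates.

    phi of the first residue and psi/omega of the last are unused.  Adds O and
    CB (CB with the exact tetrahedral-angle solve).  Useful for Ramachandran
    fixtures (e.g. fully extended phi = psi = 180) and cis-bond tests.
    """
    geom = geometry or IdealGeometry.default()
    phi = np.atleast_1d(np.asarray(phi_deg, float))
    n = len(phi)
    psi = np.broadcast_to(np.asarray(psi_deg, float), (n,))
    omega = np.broadcast_to(np.asarray(omega_deg, float), (n,))
    if isinstance(resnames, str):
        resnames = [resnames] * n

    # seed atoms of residue 0
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([geom.n_ca, 0.0, 0.0])]
    ang = math.radians(geom.theta_NC)
    C = [CA[0] + geom.ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(place_internal(N[i - 1], CA[i - 1], C[i - 1],
                                geom.c_n, geom.ang_ca_c_n, psi[i - 1]))
        CA.append(place_internal(CA[i - 1], C[i - 1], N[i],
                                 geom.n_ca, geom.ang_c_n_ca, omega[i - 1]))
        C.append(place_internal(C[i - 1], N[i], CA[i],
                                geom.ca_c, geom.theta_NC, phi[i]))
    residues = []
    for i in range(n):
        res = ResidueRecord(resname=resnames[i], seqnum=i + 1)
        atoms = {"N": N[i], "CA": CA[i], "C": C[i]}
        if i < n - 1:
            u1 = unit(CA[i] - C[i])
            u2 = unit(N[i + 1] - C[i])
            atoms["O"] = C[i] + geom.c_o * unit(-(u1 + u2))
        if resnames[i] != "GLY":
            atoms["CB"] = _solve_cb(CA[i], unit(N[i] - CA[i]), unit(C[i] - CA[i]), geom)
        for name, coord in atoms.items():
            res.atoms.append(AtomRecord(name=name, element=_elem(name), coord=coord))
        residues.append(res)
    chain = ChainModel(pdb_id="DIHE", chain_id="A", residues=residues)
    _detect_breaks(chain)
    _annotate_isomers(chain)
    return chain
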