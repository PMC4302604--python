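"""Stratified spherical density maps, tetrahedral-angle statistics, rotamer
classification and density-based outlier scoring.

Density maps are equal-area spherical histograms (uniform in cos latitude and
in longitude) smoothed with a von Mises-Fisher-style kernel.  The smoothed map
is the reference object both for outlier scoring (quantile of an atom's
reference density) and for the placement library used in C-alpha trace
reconstruction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry
from .frames import (
    SphericalDirection,
    build_side_chain_frame,
    chain_frenet_frames,
    chi_dihedral,
    direction_in_frame,
)
from .structure_io import ChainModel, ResidueRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TetrahedralAngles",
    "StratumKey",
    "DensityMap",
    "AngleSummary",
    "OutlierReport",
    "tetrahedral_angles",
    "angle_statistics",
    "angle_table",
    "build_density_map",
    "classify_rotamer",
    "score_outliers",
    "collect_observations",
]


@dataclass
class TetrahedralAngles:
    """The three heavy-atom bond angles at the C-alpha vertex, degrees.

    theta_NC = N-CA-C, theta_Nbeta = N-CA-CB, theta_betaC = CB-CA-C; entries
    are None where the defining atoms are missing (e.g. GLY has no CB).
    """

    theta_NC: float | None = None
    theta_Nbeta: float | None = None
    theta_betaC: float | None = None


def tetrahedral_angles(residue: ResidueRecord) -> TetrahedralAngles:
    """Bond angles of the covalent tetrahedron centred on CA, in degrees."""
    from .geometry import bond_angle_deg

    n, ca, c, cb = (residue.coord(a) for a in ("N", "CA", "C", "CB"))
    out = TetrahedralAngles()
    if ca is None:
        return out
    if n is not None and c is not None:
        out.theta_NC = bond_angle_deg(n, ca, c)
    if n is not None and cb is not None:
        out.theta_Nbeta = bond_angle_deg(n, ca, cb)
    if cb is not None and c is not None:
        out.theta_betaC = bond_angle_deg(cb, ca, c)
    return out


@dataclass
class AngleSummary:
    stratum: str
    angle: str
    n: int
    mean: float
    sd: float  # population convention (divide by n)


def angle_statistics(
    values: dict[str, dict[str, list[float]]]
) -> list[AngleSummary]:
    """Mean and one-sigma (population sd) per stratum and angle.

    ``values[stratum][angle]`` is a list of observations in degrees; empty
    strata are omitted with a log entry.
    """
    out = []
    for stratum, per_angle in values.items():
        for angle, obs in per_angle.items():
            if not obs:
                logger.info("empty stratum %s/%s omitted", stratum, angle)
                continue
            arr = np.asarray(obs, float)
            out.append(
                AngleSummary(
                    stratum=stratum,
                    angle=angle,
                    n=len(arr),
                    mean=float(arr.mean()),
                    sd=float(arr.std(ddof=0)),
                )
            )
    return out


def angle_table(chains: list[ChainModel], stratify: str = "ss") -> pd.DataFrame:
    """Tetrahedral-angle summary table over a set of chains.

    stratify = "ss"      -> helix / strand / loop (left-handed helices counted
                            with loops for the table, as a separate row when present)
    stratify = "cis_pro" -> cis-prolines only
    stratify = "pro"     -> All / PRO / Rest
    """
    buckets: dict[str, dict[str, list[float]]] = {}

    def push(stratum: str, ang: TetrahedralAngles):
        d = buckets.setdefault(
            stratum, {"theta_NC": [], "theta_Nbeta": [], "theta_betaC": []}
        )
        for name in d:
            v = getattr(ang, name)
            if v is not None:
                d[name].append(v)

    for chain in chains:
        for res in chain.residues:
            ang = tetrahedral_angles(res)
            if stratify == "ss":
                push(res.ss_label, ang)
            elif stratify == "cis_pro":
                if res.resname == "PRO" and res.isomer_preceding == "cis":
                    push("cis-PRO", ang)
            elif stratify == "pro":
                push("All", ang)
                push("PRO" if res.resname == "PRO" else "Rest", ang)
            else:
                raise ValueError(f"unknown stratification {stratify!r}")
    rows = [asdict(s) for s in angle_statistics(buckets)]
    return pd.DataFrame(rows, columns=["stratum", "angle", "n", "mean", "sd"])


# -- rotamer classification ---------------------------------------------------

ROTAMER_CENTERS = {"g+": 60.0, "g-": -60.0, "t": 180.0}


def classify_rotamer(chi_longitude_deg: float, gplus_positive: bool = True) -> str:
    """Nearest-of-three rotamer label for a chi longitude in degrees.

    Windows of +/-60 deg around +60 (g+), -60 (g-) and 180 (t) cover the
    circle; exact boundary values (0, +/-120, 180... the midpoints) go to the
    clockwise-lower label: g+ = (0, 120], g- = [-120, 0], t = the rest.
    With ``gplus_positive=False`` the g+/g- naming is swapped (the sign
    convention is not fixed by the field).
    """
    lon = ((chi_longitude_deg + 180.0) % 360.0) - 180.0
    if lon == -180.0:
        lon = 180.0
    if 0.0 < lon <= 120.0:
        label = "g+"
    elif -120.0 <= lon <= 0.0:
        label = "g-"
    else:
        label = "t"
    if not gplus_positive and label in ("g+", "g-"):
        label = "g-" if label == "g+" else "g+"
    return label


# -- strata -------------------------------------------------------------------


@dataclass(frozen=True)
class StratumKey:
    """Hashable stratification key; "any" is a wildcard for each field."""

    atom_level: str = "any"  # beta..eta, backbone-N/-C/-O
    atom_name: str = "any"
    residue_class: str = "any"  # resname or aromatic/non-aromatic
    ss: str = "any"
    rotamer: str = "any"  # g+ / g- / t / other / any
    context: str = "any"

    def matches(self, other: "StratumKey") -> bool:
        for f in ("atom_level", "atom_name", "residue_class", "ss", "rotamer", "context"):
            a, b = getattr(self, f), getattr(other, f)
            if a != "any" and b != "any" and a != b:
                return False
        return True

    def generalise(self, drop: str) -> "StratumKey":
        d = asdict(self)
        d[drop] = "any"
        return StratumKey(**d)


# -- density maps -------------------------------------------------------------


class DensityMap:
    """Equal-area spherical histogram with von Mises-Fisher smoothing.

    Binning is uniform in cos(latitude) (n_lat bins) and in longitude (n_lon
    bins), so every bin subtends exactly the same solid angle.  Smoothing
    convolves the counts with exp(kappa_c * (cos angular distance - 1)) where
    kappa_c = 1 / bandwidth^2 (bandwidth in radians), then normalises the grid
    to sum to 1.
    """

    def __init__(self, n_lat: int = 90, n_lon: int = 180, stratum: StratumKey | None = None):
        if n_lat < 1 or n_lon < 1:
            raise ValueError("grid must have at least one bin per axis")
        self.n_lat = n_lat
        self.n_lon = n_lon
        self.stratum = stratum or StratumKey()
        self.counts = np.zeros((n_lat, n_lon), dtype=np.int64)
        self._smoothed: np.ndarray | None = None
        self.bandwidth_deg: float | None = None

    # bin edges: cos(lat) from 1 down to -1; lon from -pi to pi
    @property
    def cos_lat_edges(self) -> np.ndarray:
        return np.linspace(1.0, -1.0, self.n_lat + 1)

    @property
    def lon_edges(self) -> np.ndarray:
        return np.linspace(-math.pi, math.pi, self.n_lon + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bin_of(self, direction: SphericalDirection) -> tuple[int, int]:
        c = math.cos(direction.latitude)
        i = int(np.clip(np.floor((1.0 - c) / 2.0 * self.n_lat), 0, self.n_lat - 1))
        j = int(
            np.clip(
                np.floor((direction.longitude + math.pi) / (2 * math.pi) * self.n_lon),
                0,
                self.n_lon - 1,
            )
        )
        return i, j

    def add(self, directions) -> "DensityMap":
        for d in directions:
            i, j = self.bin_of(d)
            self.counts[i, j] += 1
        self._smoothed = None
        return self

    def bin_centers_xyz(self) -> np.ndarray:
        """(n_lat, n_lon, 3) unit vectors at bin centers (midpoint in cos-lat)."""
        ce = self.cos_lat_edges
        cos_c = 0.5 * (ce[:-1] + ce[1:])
        sin_c = np.sqrt(np.clip(1.0 - cos_c ** 2, 0.0, None))
        le = self.lon_edges
        lon_c = 0.5 * (le[:-1] + le[1:])
        x = sin_c[:, None] * np.cos(lon_c)[None, :]
        y = sin_c[:, None] * np.sin(lon_c)[None, :]
        z = np.broadcast_to(cos_c[:, None], x.shape)
        # axes order (t, n, b): latitude measured from t
        return np.stack([z, x, y], axis=-1)

    def smooth(self, bandwidth_deg: float = 5.0) -> np.ndarray:
        """Smoothed, normalised frequency grid (sums to 1)."""
        if self.total == 0:
            raise ValueError("cannot smooth an empty density map")
        if self._smoothed is not None and self.bandwidth_deg == bandwidth_deg:
            return self._smoothed
        centers = self.bin_centers_xyz().reshape(-1, 3)
        nz = np.nonzero(self.counts.reshape(-1))[0]
        if bandwidth_deg <= 0:
            sm = self.counts.astype(float)
        else:
            conc = 1.0 / math.radians(bandwidth_deg) ** 2
            src = centers[nz]  # (M, 3)
            w = self.counts.reshape(-1)[nz].astype(float)
            # exp(conc * (cos d - 1)) keeps magnitudes bounded at 1
            dots = centers @ src.T  # (B, M)
            sm = (np.exp(conc * (dots - 1.0)) * w[None, :]).sum(axis=1)
            sm = sm.reshape(self.n_lat, self.n_lon)
        sm = sm / sm.sum()
        self._smoothed = sm
        self.bandwidth_deg = bandwidth_deg
        return sm

    def density_at(self, direction: SphericalDirection, bandwidth_deg: float = 5.0) -> float:
        sm = self.smooth(bandwidth_deg)
        i, j = self.bin_of(direction)
        return float(sm[i, j])

    def mode_direction(self, bandwidth_deg: float = 5.0) -> SphericalDirection:
        """Bin-center direction of the smoothed-density maximum."""
        sm = self.smooth(bandwidth_deg)
        i, j = np.unravel_index(int(np.argmax(sm)), sm.shape)
        ce = self.cos_lat_edges
        lat = math.acos(float(np.clip(0.5 * (ce[i] + ce[i + 1]), -1, 1)))
        le = self.lon_edges
        lon = float(0.5 * (le[j] + le[j + 1]))
        return SphericalDirection(latitude=lat, longitude=lon)

    def bin_solid_angles(self) -> np.ndarray:
        ce = self.cos_lat_edges
        d_cos = ce[:-1] - ce[1:]
        d_lon = 2 * math.pi / self.n_lon
        return np.broadcast_to((d_cos * d_lon)[:, None], (self.n_lat, self.n_lon)).copy()

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_lat": self.n_lat,
            "n_lon": self.n_lon,
            "stratum": asdict(self.stratum),
            "counts": self.counts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityMap":
        dm = cls(d["n_lat"], d["n_lon"], StratumKey(**d["stratum"]))
        dm.counts = np.asarray(d["counts"], dtype=np.int64)
        return dm

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "DensityMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_density_map(
    directions,
    stratum: StratumKey | None = None,
    n_lat: int = 90,
    n_lon: int = 180,
    bandwidth_deg: float = 5.0,
) -> DensityMap:
    """Equal-area histogram of directions, pre-smoothed at ``bandwidth_deg``."""
    directions = list(directions)
    if not directions:
        raise ValueError("cannot build a density map from zero directions")
    dm = DensityMap(n_lat=n_lat, n_lon=n_lon, stratum=stratum).add(directions)
    dm.smooth(bandwidth_deg)
    return dm


# -- outlier scoring ----------------------------------------------------------


@dataclass
class OutlierReport:
    atom_ref: tuple  # (chain_id, residue index, atom name)
    stratum: StratumKey
    density_quantile: float
    flagged: bool
    scorable: bool = True


def score_outliers(
    observations,
    reference: DensityMap,
    threshold_quantile: float = 0.005,
    bandwidth_deg: float = 5.0,
) -> list[OutlierReport]:
    """Flag atoms whose reference density falls below a quantile threshold.

    ``observations`` is an iterable of (atom_ref, SphericalDirection).  Each
    atom's smoothed reference density is converted to a quantile among the
    reference's own per-observation densities; atoms strictly below the
    threshold quantile are flagged.
    """
    sm = reference.smooth(bandwidth_deg)
    # empirical distribution of densities of the reference observations
    ref_densities = np.repeat(sm.reshape(-1), reference.counts.reshape(-1))
    ref_densities.sort()
    n_ref = len(ref_densities)
    out = []
    for atom_ref, direction in observations:
        d = sm[reference.bin_of(direction)]
        q = float(np.searchsorted(ref_densities, d, side="left")) / n_ref
        out.append(
            OutlierReport(
                atom_ref=atom_ref,
                stratum=reference.stratum,
                density_quantile=q,
                flagged=q < threshold_quantile,
            )
        )
    return out


# -- observation collection ---------------------------------------------------


def collect_observations(
    chains: list[ChainModel],
    level: str,
    frame: str = "frenet",
    center: str = "distal",
    split_aromatic: bool | None = None,
) -> pd.DataFrame:
    """Directions (and radii) of the atoms of one level over a set of chains.

    frame = "frenet" observes from the residue's backbone Frenet frame
    (C-alpha centered); "chi1" uses the chi1 framing; "zx" (or "chi2", its
    delta-level special case) uses the Z-X framing along the side-chain path.
    Columns: pdb_id, chain, idx, resnum, resname, residue_class, ss, rotamer,
    atom, level, latitude, longitude (radians), latitude_deg, longitude_deg,
    radius.
    """
    if split_aromatic is None:
        split_aromatic = level in ("delta", "epsilon", "zeta", "eta")
    rows = []
    for chain in chains:
        frenet = chain_frenet_frames(chain)
        for i, res in enumerate(chain.residues):
            bb = frenet[i]
            targets = _level_targets(res, level)
            if not targets:
                continue
            chi1 = chi_dihedral(res, 1)
            rot = classify_rotamer(math.degrees(chi1)) if chi1 is not None else "other"
            for atom_name in targets:
                coord = res.coord(atom_name)
                if coord is None:
                    continue
                fr = _observation_frame(res, level, frame, bb, center)
                if fr is None:
                    continue
                try:
                    direction = direction_in_frame(fr, coord)
                except ValueError:
                    continue
                radius = float(np.linalg.norm(coord - fr.origin))
                rows.append(
                    {
                        "pdb_id": chain.pdb_id,
                        "chain": chain.chain_id,
                        "idx": i,
                        "resnum": res.seqnum,
                        "resname": res.resname,
                        "residue_class": chemistry.residue_class(res.resname, split_aromatic),
                        "ss": res.ss_label,
                        "rotamer": rot,
                        "atom": atom_name,
                        "level": level,
                        "latitude": direction.latitude,
                        "longitude": direction.longitude,
                        "latitude_deg": direction.latitude_deg,
                        "longitude_deg": direction.longitude_deg,
                        "radius": radius,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "pdb_id", "chain", "idx", "resnum", "resname", "residue_class", "ss",
            "rotamer", "atom", "level", "latitude", "longitude", "latitude_deg",
            "longitude_deg", "radius",
        ],
    )


def _level_targets(res: ResidueRecord, level: str) -> tuple[str, ...]:
    if level == "backbone-N":
        return ("N",)
    if level == "backbone-C":
        return ("C",)
    if level == "backbone-O":
        return ("O",)
    atom = chemistry.level_atom(res.resname, level)
    return (atom,) if atom else ()


def _observation_frame(res, level, frame, bb_frame, center):
    if frame == "frenet":
        return bb_frame
    if frame == "chi1":
        return build_side_chain_frame(res, "chi1")
    if frame in ("zx", "chi2"):
        if bb_frame is None:
            return None
        lvl = "delta" if frame == "chi2" else level
        return build_side_chain_frame(res, lvl, backbone_tangent=bb_frame.t, origin=center)
    raise ValueError(f"unknown frame kind {frame!r}")
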