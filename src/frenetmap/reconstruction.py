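"""Proof-of-concept C-alpha trace solver.

Every heavy atom is encoded as a (frame, direction, radius) triple.  A
placement library learned from full structures stores, per stratum (atom
level and name, residue class, secondary structure, rotamer), the modal
direction of the smoothed spherical density map together with the mean
radius.  Reconstruction builds the Frenet frames of a bare C-alpha trace,
places N, C, O and C-beta from the backbone strata, and then climbs each side
chain placing the gamma..eta path atoms sequentially in Z-X frames anchored
on the atoms already placed, so the whole rebuild depends on the C-alpha
coordinates only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import chemistry
from .frames import (
    FrenetFrame,
    SphericalDirection,
    build_frenet_frames,
    direction_in_frame,
    zx_frame,
)
from .maps_stats import DensityMap, StratumKey, collect_observations
from .structure_io import AtomRecord, ChainModel, ResidueRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PlacementEntry",
    "PlacementLibrary",
    "ReconstructionResult",
    "encode_atom",
    "decode_atom",
    "build_placement_library",
    "reconstruct_chain",
]

#: wildcard order tried when a stratum has no library entry
FALLBACK_ORDER = ("rotamer", "context", "ss")

_ELEMENT = {"N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT.get(atom_name[0], "C")


def encode_atom(frame: FrenetFrame, coord: np.ndarray) -> tuple[SphericalDirection, float]:
    """(direction, radius) of an atom as seen from a frame."""
    direction = direction_in_frame(frame, coord)
    radius = float(np.linalg.norm(np.asarray(coord, float) - frame.origin))
    if radius <= 0:
        raise ValueError("zero radius: atom coincides with frame origin")
    return direction, radius


def decode_atom(frame: FrenetFrame, direction: SphericalDirection, radius: float) -> np.ndarray:
    """Inverse of :func:`encode_atom`: a coordinate from (frame, direction, radius)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    k, t = direction.latitude, direction.longitude
    u = (
        math.cos(k) * frame.t
        + math.sin(k) * math.cos(t) * frame.n
        + math.sin(k) * math.sin(t) * frame.b
    )
    return frame.origin + radius * u


@dataclass
class PlacementEntry:
    stratum: StratumKey
    modal_direction: SphericalDirection
    mean_radius: float
    dispersion: float  # mean resultant length of the direction sample, in [0, 1]
    n: int

    def to_dict(self) -> dict:
        return {
            "stratum": asdict(self.stratum),
            "latitude": self.modal_direction.latitude,
            "longitude": self.modal_direction.longitude,
            "mean_radius": self.mean_radius,
            "dispersion": self.dispersion,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlacementEntry":
        return cls(
            stratum=StratumKey(**d["stratum"]),
            modal_direction=SphericalDirection(d["latitude"], d["longitude"]),
            mean_radius=d["mean_radius"],
            dispersion=d["dispersion"],
            n=d["n"],
        )


@dataclass
class PlacementLibrary:
    entries: dict[StratumKey, PlacementEntry] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, entry: PlacementEntry) -> None:
        self.entries[entry.stratum] = entry

    def lookup(self, key: StratumKey) -> tuple[PlacementEntry | None, int]:
        """Entry for a stratum, generalising along the documented wildcard
        order (drop rotamer -> drop context -> drop ss); returns the entry and
        the fallback depth (0 = exact)."""
        k = key
        for depth, drop in enumerate((None,) + FALLBACK_ORDER):
            if drop is not None:
                k = k.generalise(drop)
            if k in self.entries:
                return self.entries[k], depth
        return None, -1

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "provenance": self.provenance,
                    "entries": [e.to_dict() for e in self.entries.values()],
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "PlacementLibrary":
        d = json.loads(Path(path).read_text())
        lib = cls(provenance=d.get("provenance", {}))
        for ed in d["entries"]:
            lib.add(PlacementEntry.from_dict(ed))
        return lib


_BACKBONE_SPECS = (("backbone-N", "N"), ("backbone-C", "C"), ("backbone-O", "O"), ("beta", "CB"))


def _library_strata(df, level: str, with_rotamer: bool):
    group_cols = ["atom", "residue_class", "ss"] + (["rotamer"] if with_rotamer else [])
    for keys, sub in df.groupby(group_cols, sort=True):
        keys = dict(zip(group_cols, keys))
        yield (
            StratumKey(
                atom_level=level,
                atom_name=keys["atom"],
                residue_class=keys["residue_class"],
                ss=keys["ss"],
                rotamer=keys.get("rotamer", "any"),
            ),
            sub,
        )


def build_placement_library(
    chains: list[ChainModel],
    levels: tuple[str, ...] = ("backbone-N", "backbone-C", "backbone-O", "beta", "gamma"),
    n_lat: int = 90,
    n_lon: int = 180,
    bandwidth_deg: float = 5.0,
    min_support: int = 25,
    resolution_cutoff: float | None = None,
) -> PlacementLibrary:
    """Learn per-stratum modal placements from labelled full-atom chains.

    Backbone levels and beta are observed in the C-alpha Frenet frame; gamma
    and higher levels in the Z-X frames of the side-chain path.  Strata with
    fewer than ``min_support`` observations are dropped; generalised entries
    (rotamer/ss wildcards) are always added as fallbacks.
    """
    lib = PlacementLibrary(
        provenance={
            "n_chains": len(chains),
            "resolution_cutoff": resolution_cutoff,
            "n_lat": n_lat,
            "n_lon": n_lon,
            "bandwidth_deg": bandwidth_deg,
            "min_support": min_support,
        }
    )
    got_any = False
    for level in levels:
        frame_kind = "frenet" if level in dict(_BACKBONE_SPECS) or level.startswith("backbone") else "zx"
        if level == "beta":
            frame_kind = "frenet"
        df = collect_observations(chains, level, frame=frame_kind, center="distal",
                                  split_aromatic=False)
        if df.empty:
            continue
        with_rot = level not in ("backbone-N", "backbone-C", "backbone-O", "beta")
        strata = list(_library_strata(df, level, with_rot))
        # generalised fallbacks: ss-wildcard and (for side chains) rotamer-wildcard
        extra = []
        for keys, sub in df.groupby(["atom", "residue_class"], sort=True):
            k = dict(zip(["atom", "residue_class"], keys))
            extra.append(
                (
                    StratumKey(atom_level=level, atom_name=k["atom"],
                               residue_class=k["residue_class"]),
                    sub,
                )
            )
        if with_rot:
            for keys, sub in df.groupby(["atom", "residue_class", "ss"], sort=True):
                k = dict(zip(["atom", "residue_class", "ss"], keys))
                extra.append(
                    (
                        StratumKey(atom_level=level, atom_name=k["atom"],
                                   residue_class=k["residue_class"], ss=k["ss"]),
                        sub,
                    )
                )
        for stratum, sub in strata + extra:
            if len(sub) < min_support:
                continue
            directions = [
                SphericalDirection(la, lo)
                for la, lo in zip(sub["latitude"], sub["longitude"])
            ]
            dm = DensityMap(n_lat=n_lat, n_lon=n_lon, stratum=stratum).add(directions)
            mode = dm.mode_direction(bandwidth_deg)
            vecs = np.array([d.as_vector() for d in directions])
            dispersion = float(np.linalg.norm(vecs.mean(axis=0)))
            lib.add(
                PlacementEntry(
                    stratum=stratum,
                    modal_direction=mode,
                    mean_radius=float(sub["radius"].mean()),
                    dispersion=dispersion,
                    n=len(sub),
                )
            )
            got_any = True
    if not got_any:
        raise ValueError(
            f"no stratum reached min_support={min_support}; "
            f"chains={len(chains)}, levels={levels}"
        )
    return lib


@dataclass
class ReconstructionResult:
    chain: ChainModel
    provenance: list[dict]  # per placed atom: stratum used, fallback depth
    rmsd_by_atom: dict[str, float] | None = None

    def rmsd_table(self):
        import pandas as pd

        if self.rmsd_by_atom is None:
            return None
        return pd.DataFrame(
            sorted(self.rmsd_by_atom.items()), columns=["atom", "rmsd_A"]
        )


def reconstruct_chain(
    ca_trace: np.ndarray,
    resnames: list[str],
    ss_labels: list[str],
    library: PlacementLibrary,
    truth: ChainModel | None = None,
    rotamers: list[str] | None = None,
) -> ReconstructionResult:
    """Rebuild heavy atoms from a C-alpha trace, residue names and ss labels.

    Interior residues (where a Frenet frame exists) get N, C, O and CB from
    the backbone strata, then the side-chain path atoms placed sequentially in
    Z-X frames.  Residues at termini are left C-alpha only.  The rotamer
    stratum defaults to the library's most populated rotamer per
    (residue class, ss); pass ``rotamers`` to override per residue.
    """
    ca = np.asarray(ca_trace, float)
    if len(ca) < 3:
        raise ValueError("trace too short: need at least 3 C-alpha positions")
    if not (len(resnames) == len(ca) == len(ss_labels)):
        raise ValueError("trace, resnames and ss_labels must have equal length")
    frames = build_frenet_frames(ca)

    residues = []
    provenance: list[dict] = []
    for i, (pos, resname, ss) in enumerate(zip(ca, resnames, ss_labels)):
        res = ResidueRecord(resname=resname, seqnum=i + 1, ss_label=ss)
        res.atoms.append(AtomRecord(name="CA", element="C", coord=pos.copy()))
        fr = frames[i]
        if fr is None or resname not in chemistry.STANDARD_RESNAMES:
            if resname not in chemistry.STANDARD_RESNAMES:
                logger.warning("unknown residue name %s at %d: left C-alpha only", resname, i)
            residues.append(res)
            continue
        path = chemistry.SIDE_CHAIN_PATH[resname]
        rotamer = rotamers[i] if rotamers is not None else None
        # backbone atoms + CB in the Frenet frame
        for level, atom_name in _BACKBONE_SPECS:
            if atom_name == "CB" and not path:
                continue  # GLY
            key = StratumKey(atom_level=level, atom_name=atom_name,
                             residue_class=resname, ss=ss)
            entry, depth = library.lookup(key)
            if entry is None:
                continue
            coord = decode_atom(fr, entry.modal_direction, entry.mean_radius)
            res.atoms.append(AtomRecord(name=atom_name, element=_element_of(atom_name),
                                        coord=coord))
            provenance.append({"idx": i, "atom": atom_name,
                               "stratum": asdict(entry.stratum), "fallback_depth": depth})
        # side-chain path atoms in sequential Z-X frames
        placed = {"CA": pos}
        for a in res.atoms:
            placed[a.name] = a.coord
        full_path = ("CA",) + path
        for level_i in range(1, len(path)):
            level = chemistry.LEVELS[level_i]
            z_name, x_name = full_path[level_i - 1], full_path[level_i]
            atom_name = full_path[level_i + 1]
            if z_name not in placed or x_name not in placed:
                break
            key = StratumKey(atom_level=level, atom_name=atom_name,
                             residue_class=resname, ss=ss,
                             rotamer=rotamer if rotamer is not None else "any")
            entry, depth = library.lookup(key)
            if entry is None and rotamer is None:
                entry, depth = _most_populated_rotamer(library, level, atom_name, resname, ss)
            if entry is None:
                break
            fr_zx = zx_frame(placed[z_name], placed[x_name], fr.t, origin="distal", level=level)
            if fr_zx is None:
                break
            coord = decode_atom(fr_zx, entry.modal_direction, entry.mean_radius)
            res.atoms.append(AtomRecord(name=atom_name, element=_element_of(atom_name),
                                        coord=coord))
            placed[atom_name] = coord
            provenance.append({"idx": i, "atom": atom_name,
                               "stratum": asdict(entry.stratum), "fallback_depth": depth,
                               "rotamer_choice": entry.stratum.rotamer})
        residues.append(res)

    chain = ChainModel(pdb_id="RECN", chain_id="A", residues=residues)
    rmsd = _rmsd_by_atom(chain, truth) if truth is not None else None
    return ReconstructionResult(chain=chain, provenance=provenance, rmsd_by_atom=rmsd)


def _most_populated_rotamer(library, level, atom_name, resname, ss):
    best, best_depth = None, -1
    for key, entry in library.entries.items():
        if (key.atom_level == level and key.atom_name == atom_name
                and key.residue_class == resname and key.ss == ss
                and key.rotamer != "any"):
            if best is None or entry.n > best.n:
                best, best_depth = entry, 0
    if best is None:
        generic = StratumKey(atom_level=level, atom_name=atom_name,
                             residue_class=resname, ss=ss)
        return library.lookup(generic)
    return best, best_depth


def _rmsd_by_atom(rebuilt: ChainModel, truth: ChainModel) -> dict[str, float]:
    sq: dict[str, list[float]] = {}
    for res_r, res_t in zip(rebuilt.residues, truth.residues):
        for a in res_r.atoms:
            if a.name == "CA":
                continue
            t = res_t.coord(a.name)
            if t is None:
                continue
            sq.setdefault(a.name, []).append(float(np.sum((a.coord - t) ** 2)))
    return {name: math.sqrt(np.mean(v)) for name, v in sq.items() if v}
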