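"""Parsing of PDB/mmCIF files into a uniform chain model.

The chain model carries, per residue, the heavy-atom coordinates, the
header-derived secondary-structure label (helix / strand / left-handed helix /
loop, following the deposited HELIX and SHEET records), the cis/trans isomerism
of the preceding peptide bond, and recorded chain breaks.  Parsing is done with
:mod:`gemmi`; hydrogens are dropped and alternate locations resolved to the
highest-occupancy conformer.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import dihedral_angle

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ChainModel",
    "ContextSelector",
    "parse_structure",
    "assign_secondary_structure",
    "classify_peptide_bond",
    "select_residue_context",
    "write_pdb",
    "save_chains_json",
    "load_chains_json",
]

SS_LABELS = ("helix", "strand", "left_handed_helix", "loop")
#: consecutive CA-CA distance beyond which a chain break is recorded (A).
BREAK_DISTANCE = 4.5
#: |omega| below this is cis (midpoint between the ideal 0 and 180 degrees).
CIS_THRESHOLD_DEG = 90.0
#: PDB HELIX class codes for left-handed alpha helices.
_LEFT_HANDED_CLASSES = {6}


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueRecord:
    resname: str
    seqnum: int
    icode: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)
    ss_label: str = "loop"
    isomer_preceding: str = "undefined"  # cis / trans / undefined

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coord


@dataclass
class ChainModel:
    pdb_id: str
    chain_id: str
    residues: list[ResidueRecord]
    resolution: float | None = None
    breaks: list[int] = field(default_factory=list)  # break between residues i and i+1

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> list[np.ndarray | None]:
        return [r.coord("CA") for r in self.residues]

    def segments(self) -> list[tuple[int, int]]:
        """Contiguous index ranges [start, stop) not spanning a break or missing CA."""
        cuts = set(self.breaks)
        segs, start = [], 0
        for i, r in enumerate(self.residues):
            if r.coord("CA") is None:
                if i > start:
                    segs.append((start, i))
                start = i + 1
            elif i in cuts:
                segs.append((start, i + 1))
                start = i + 1
        if len(self.residues) > start:
            segs.append((start, len(self.residues)))
        return [s for s in segs if s[1] - s[0] >= 1]

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pdb_id": self.pdb_id,
            "chain_id": self.chain_id,
            "resolution": self.resolution,
            "breaks": list(self.breaks),
            "residues": [
                {
                    "resname": r.resname,
                    "seqnum": r.seqnum,
                    "icode": r.icode,
                    "ss_label": r.ss_label,
                    "isomer_preceding": r.isomer_preceding,
                    "atoms": [
                        {
                            "name": a.name,
                            "element": a.element,
                            "coord": [round(float(c), 3) for c in a.coord],
                            "occupancy": a.occupancy,
                            "altloc": a.altloc,
                        }
                        for a in r.atoms
                    ],
                }
                for r in self.residues
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainModel":
        residues = [
            ResidueRecord(
                resname=rd["resname"],
                seqnum=rd["seqnum"],
                icode=rd.get("icode", ""),
                ss_label=rd.get("ss_label", "loop"),
                isomer_preceding=rd.get("isomer_preceding", "undefined"),
                atoms=[
                    AtomRecord(
                        name=ad["name"],
                        element=ad["element"],
                        coord=np.array(ad["coord"], float),
                        occupancy=ad.get("occupancy", 1.0),
                        altloc=ad.get("altloc", ""),
                    )
                    for ad in rd["atoms"]
                ],
            )
            for rd in d["residues"]
        ]
        return cls(
            pdb_id=d["pdb_id"],
            chain_id=d["chain_id"],
            residues=residues,
            resolution=d.get("resolution"),
            breaks=list(d.get("breaks", [])),
        )


@dataclass(frozen=True)
class ContextSelector:
    """Residue-context filter; selectors compose by intersection."""

    kind: str  # all | terminal_two | before_cis_pro | after_cis_pro |
    #           before_trans_pro | after_trans_pro | by_resname | by_ss | by_rotamer
    params: tuple = ()

    KINDS = (
        "all",
        "terminal_two",
        "before_cis_pro",
        "after_cis_pro",
        "before_trans_pro",
        "after_trans_pro",
        "by_resname",
        "by_ss",
        "by_rotamer",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown context selector kind {self.kind!r}")


# ---------------------------------------------------------------------------


def classify_peptide_bond(res_i: ResidueRecord, res_next: ResidueRecord) -> str:
    """cis/trans isomerism of the peptide bond between two consecutive residues.

    The omega dihedral CA(i)-C(i)-N(i+1)-CA(i+1) is computed; |omega| < 90 deg
    is cis, otherwise trans.  Missing atoms or degenerate geometry give
    "undefined".
    """
    pts = (res_i.coord("CA"), res_i.coord("C"), res_next.coord("N"), res_next.coord("CA"))
    if any(p is None for p in pts):
        return "undefined"
    try:
        omega = dihedral_angle(*pts)
    except ValueError:
        warnings.warn("degenerate peptide-bond geometry; isomer undefined")
        return "undefined"
    return "cis" if abs(np.degrees(omega)) < CIS_THRESHOLD_DEG else "trans"


def assign_secondary_structure(
    chain: ChainModel,
    helix_ranges: list[tuple[int, int, int]] = (),
    sheet_ranges: list[tuple[int, int]] = (),
) -> ChainModel:
    """Label residues from header helix/sheet ranges (inclusive seqnum ranges).

    ``helix_ranges`` entries are (start, end, pdb_helix_class); class 6
    (left-handed alpha) maps to ``left_handed_helix``.  Helix wins on overlap
    with sheets (warning logged); everything else is loop.
    """
    in_sheet = {}
    for start, end in sheet_ranges:
        for s in range(start, end + 1):
            in_sheet[s] = True
    in_helix = {}
    for start, end, hclass in helix_ranges:
        label = "left_handed_helix" if hclass in _LEFT_HANDED_CLASSES else "helix"
        for s in range(start, end + 1):
            in_helix[s] = label
            if s in in_sheet:
                logger.warning(
                    "residue %s in chain %s is in both HELIX and SHEET ranges; helix wins",
                    s,
                    chain.chain_id,
                )
    for r in chain.residues:
        if r.seqnum in in_helix:
            r.ss_label = in_helix[r.seqnum]
        elif r.seqnum in in_sheet:
            r.ss_label = "strand"
        else:
            r.ss_label = "loop"
    return chain


def _detect_breaks(chain: ChainModel) -> None:
    chain.breaks = []
    for i in range(len(chain.residues) - 1):
        a = chain.residues[i].coord("CA")
        b = chain.residues[i + 1].coord("CA")
        if a is not None and b is not None and np.linalg.norm(b - a) > BREAK_DISTANCE:
            chain.breaks.append(i)


def _annotate_isomers(chain: ChainModel) -> None:
    cuts = set(chain.breaks)
    chain.residues[0].isomer_preceding = "undefined"
    for i in range(1, len(chain.residues)):
        if (i - 1) in cuts:
            chain.residues[i].isomer_preceding = "undefined"
        else:
            chain.residues[i].isomer_preceding = classify_peptide_bond(
                chain.residues[i - 1], chain.residues[i]
            )


def _resolve_altlocs(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    by_name: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
        elif policy == "first":
            kept.append(group[0])
        else:  # highest occupancy, alphabetical altloc tie-break
            kept.append(max(group, key=lambda a: (a.occupancy, _neg_ord(a.altloc))))
    return kept


def _neg_ord(altloc: str) -> float:
    return -ord(altloc) if altloc else 0.0


_PDB_RECORDS = (
    "HEADER", "ATOM", "HETATM", "REMARK", "CRYST1", "MODEL", "HELIX", "SHEET",
    "SEQRES", "TER", "END", "TITLE", "COMPND", "EXPDTA", "data_", "loop_", "#",
)


def _looks_like_structure_text(path: Path) -> bool:
    try:
        head = path.read_text(errors="replace")[:4000]
    except OSError:
        return False
    return any(
        line.startswith(_PDB_RECORDS) for line in head.splitlines() if line.strip()
    )


def parse_structure(
    path: str | Path,
    max_resolution: float | None = None,
    altloc_policy: str = "occupancy",
) -> list[ChainModel]:
    """Parse a PDB or mmCIF file into one ChainModel per polypeptide chain.

    Heavy atoms only (hydrogens dropped); alternate locations resolved per
    ``altloc_policy``; the first model only for multi-model files.  When
    ``max_resolution`` is given, entries with worse (or missing) resolution
    return no chains.
    """
    if max_resolution is not None and max_resolution <= 0:
        raise ValueError("max_resolution must be positive")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"cannot parse structure file {path}: no models found")
    if len(st[0]) == 0 and not _looks_like_structure_text(path):
        raise ValueError(
            f"cannot parse structure file {path}: no recognisable PDB/mmCIF records"
        )
    st.setup_entities()
    resolution = float(st.resolution) if st.resolution > 0 else None
    if max_resolution is not None:
        if resolution is None or resolution > max_resolution:
            return []

    helix_by_chain: dict[str, list[tuple[int, int, int]]] = {}
    for h in st.helices:
        hclass = int(h.pdb_helix_class.value)
        helix_by_chain.setdefault(h.start.chain_name, []).append(
            (h.start.res_id.seqid.num, h.end.res_id.seqid.num, hclass)
        )
    sheet_by_chain: dict[str, list[tuple[int, int]]] = {}
    for sheet in st.sheets:
        for strand in sheet.strands:
            sheet_by_chain.setdefault(strand.start.chain_name, []).append(
                (strand.start.res_id.seqid.num, strand.end.res_id.seqid.num)
            )

    chains: list[ChainModel] = []
    model = st[0]  # first model only
    for ch in model:
        polymer = ch.get_polymer()
        if polymer.length() == 0 or not polymer.check_polymer_type() in (
            gemmi.PolymerType.PeptideL,
            gemmi.PolymerType.PeptideD,
        ):
            continue
        residues = []
        for res in polymer:
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=float(a.occ),
                    altloc=a.altloc if a.altloc else "",
                )
                for a in res
                if not a.is_hydrogen()
            ]
            atoms = _resolve_altlocs(atoms, altloc_policy)
            residues.append(
                ResidueRecord(
                    resname=res.name,
                    seqnum=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    atoms=atoms,
                )
            )
        if not residues:
            continue
        cm = ChainModel(
            pdb_id=st.name or path.stem,
            chain_id=ch.name,
            residues=residues,
            resolution=resolution,
        )
        assign_secondary_structure(
            cm, helix_by_chain.get(ch.name, []), sheet_by_chain.get(ch.name, [])
        )
        _detect_breaks(cm)
        _annotate_isomers(cm)
        chains.append(cm)
    return chains


# -- residue-context selection ----------------------------------------------


def _single_context(chain: ChainModel, sel: ContextSelector) -> set[int]:
    n = len(chain.residues)
    if sel.kind == "all":
        return set(range(n))
    if sel.kind == "terminal_two":
        idx = {0, 1, n - 2, n - 1} if n >= 2 else {0}
        return {i for i in idx if 0 <= i < n}
    if sel.kind in ("before_cis_pro", "before_trans_pro", "after_cis_pro", "after_trans_pro"):
        isomer = "cis" if "cis" in sel.kind else "trans"
        out = set()
        for i, r in enumerate(chain.residues):
            if r.resname != "PRO" or r.isomer_preceding != isomer:
                continue
            j = i - 1 if sel.kind.startswith("before") else i + 1
            if 0 <= j < n:
                out.add(j)
        return out
    if sel.kind == "by_resname":
        names = set(sel.params)
        return {i for i, r in enumerate(chain.residues) if r.resname in names}
    if sel.kind == "by_ss":
        labels = set(sel.params)
        return {i for i, r in enumerate(chain.residues) if r.ss_label in labels}
    if sel.kind == "by_rotamer":
        # resolved downstream where chi angles are available; here a no-op filter
        return set(range(n))
    raise AssertionError(sel.kind)


def select_residue_context(chain: ChainModel, *selectors: ContextSelector) -> list[int]:
    """Indices of residues matching the intersection of the given selectors."""
    if not chain.residues:
        raise ValueError("chain has no residues")
    if not selectors:
        selectors = (ContextSelector("all"),)
    result = None
    for sel in selectors:
        s = _single_context(chain, sel)
        result = s if result is None else (result & s)
    return sorted(result)


# -- output -------------------------------------------------------------------


def write_pdb(chains: list[ChainModel], path: str | Path, resolution: float | None = None) -> None:
    """Write chains as a standard PDB file (ATOM records, HELIX/SHEET headers)."""
    st = gemmi.Structure()
    st.name = chains[0].pdb_id if chains else "XXXX"
    res_set = resolution if resolution is not None else (chains[0].resolution if chains else None)
    if res_set is not None:
        st.resolution = float(res_set)
    model = gemmi.Model("1")
    serial = 1
    for cm in chains:
        ch = gemmi.Chain(cm.chain_id)
        for r in cm.residues:
            res = gemmi.Residue()
            res.name = r.resname
            res.seqid = gemmi.SeqId(r.seqnum, r.icode or " ")
            res.het_flag = "A"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coord)
                atom.occ = a.occupancy
                atom.altloc = a.altloc if a.altloc else "\0"
                atom.serial = serial
                serial += 1
                res.add_atom(atom)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    # header secondary structure back out as HELIX/SHEET
    for cm in chains:
        _emit_ss_records(st, cm)
    st.write_pdb(str(path))


def _emit_ss_records(st: gemmi.Structure, cm: ChainModel) -> None:
    def runs(label_pred):
        out, start = [], None
        for i, r in enumerate(cm.residues):
            if label_pred(r.ss_label):
                if start is None:
                    start = i
            elif start is not None:
                out.append((start, i - 1))
                start = None
        if start is not None:
            out.append((start, len(cm.residues) - 1))
        return out

    for s, e in runs(lambda l: l in ("helix", "left_handed_helix")):
        h = gemmi.Helix()
        addr = gemmi.AtomAddress()
        h.start = _address(cm, s)
        h.end = _address(cm, e)
        h.pdb_helix_class = gemmi.Helix.HelixClass(
            6 if cm.residues[s].ss_label == "left_handed_helix" else 1
        )
        h.length = e - s + 1
        st.helices.append(h)
        del addr
    strand_runs = runs(lambda l: l == "strand")
    if strand_runs:
        sheet = gemmi.Sheet(f"S{cm.chain_id}")
        for s, e in strand_runs:
            strand = gemmi.Sheet.Strand()
            strand.start = _address(cm, s)
            strand.end = _address(cm, e)
            strand.sense = 0
            sheet.strands.append(strand)
        st.sheets.append(sheet)


def _address(cm: ChainModel, i: int) -> gemmi.AtomAddress:
    addr = gemmi.AtomAddress()
    addr.chain_name = cm.chain_id
    addr.res_id = gemmi.ResidueId()
    addr.res_id.name = cm.residues[i].resname
    addr.res_id.seqid = gemmi.SeqId(cm.residues[i].seqnum, cm.residues[i].icode or " ")
    return addr


def save_chains_json(chains: list[ChainModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in chains], indent=1))


def load_chains_json(path: str | Path) -> list[ChainModel]:
    return [ChainModel.from_dict(d) for d in json.loads(Path(path).read_text())]
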