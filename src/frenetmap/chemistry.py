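"""Amino-acid heavy-atom topology used by the sphere-map levels.

Side chains are walked level by level (beta, gamma, delta, epsilon, zeta, eta)
along a single observation path per residue type.  Where a level is branched
the path follows the atom the next level hangs off: ILE uses CG1 (the gamma
carbon bonded to CD1), TRP and HIS use CD2.  For PHE/TYR the two ring branches
are equivalent and CD1 is used.
"""

from __future__ import annotations

AROMATIC = frozenset({"PHE", "TYR", "TRP", "HIS"})

#: ordered heavy-atom observation path beyond CA, index 0 = beta level
SIDE_CHAIN_PATH: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "THR": ("CB", "OG1"),
    "VAL": ("CB", "CG1"),
    "ILE": ("CB", "CG1", "CD1"),
    "LEU": ("CB", "CG", "CD1"),
    "PRO": ("CB", "CG", "CD"),
    "ASP": ("CB", "CG", "OD1"),
    "ASN": ("CB", "CG", "OD1"),
    "GLU": ("CB", "CG", "CD", "OE1"),
    "GLN": ("CB", "CG", "CD", "OE1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH2"),
    "PHE": ("CB", "CG", "CD1", "CE1", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CE1", "CZ", "OH"),
    "TRP": ("CB", "CG", "CD2", "CE2", "CZ2", "CH2"),
    "HIS": ("CB", "CG", "CD2", "NE2"),
}

LEVELS = ("beta", "gamma", "delta", "epsilon", "zeta", "eta")
BACKBONE_LEVELS = ("backbone-N", "backbone-C", "backbone-O")
LEVEL_INDEX = {name: i for i, name in enumerate(LEVELS)}

STANDARD_RESNAMES = frozenset(SIDE_CHAIN_PATH)


def level_atom(resname: str, level: str) -> str | None:
    """PDB name of the path atom of ``resname`` at ``level`` (None if absent)."""
    path = SIDE_CHAIN_PATH.get(resname)
    if path is None:
        return None
    i = LEVEL_INDEX[level]
    return path[i] if i < len(path) else None


def residue_class(resname: str, split_aromatic: bool = False) -> str:
    """Stratification class of a residue: its name, or the aromatic bisection."""
    if split_aromatic:
        return "aromatic" if resname in AROMATIC else "non-aromatic"
    return resname
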