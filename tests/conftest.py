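import numpy as np
import pytest

import frenetmap as fm

# -- synthetic chains ---------------------------------------------------------


@pytest.fixture(scope="session")
def helix_trace():
    return fm.generate_trace(fm.HelixParams(n_residues=20))


@pytest.fixture(scope="session")
def helix_chain():
    trace = fm.generate_trace(fm.HelixParams(n_residues=20))
    return fm.generate_ideal_backbone(
        trace, resnames="LEU", chi1_deg=-60.0, chi2_deg=175.0, ss_label="helix"
    )


@pytest.fixture(scope="session")
def strand_chain():
    trace = fm.generate_trace(fm.StrandParams(n_residues=20))
    return fm.generate_ideal_backbone(
        trace, resnames="VAL", chi1_deg=180.0, ss_label="strand"
    )


@pytest.fixture(scope="session")
def training_chains():
    """Noisy helix+strand chains with gamma/delta atoms, for library tests."""
    chains = []
    for seed in range(4):
        tr = fm.generate_trace(fm.HelixParams(n_residues=30))
        chains.append(
            fm.generate_ideal_backbone(
                tr, resnames="LEU", chi1_deg=-60.0, chi2_deg=175.0,
                noise_sd=0.02, seed=seed, ss_label="helix",
            )
        )
        ts = fm.generate_trace(fm.StrandParams(n_residues=30))
        chains.append(
            fm.generate_ideal_backbone(
                ts, resnames="LEU", chi1_deg=-60.0, chi2_deg=175.0,
                noise_sd=0.02, seed=100 + seed, ss_label="strand",
            )
        )
    return chains


# -- hand-written PDB fixture -------------------------------------------------


def _atom_line(serial, name, altloc, resname, chain, resnum, xyz, occ=1.0, element=" C"):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:>3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}  0.00          {element}\n"
    )


def make_tripeptide_pdb(resolution=0.95, altloc_cb=False, with_hydrogen=True):
    """ALA-GLY-PRO text fixture with HELIX/SHEET records and 3-decimal coords.

    Residue 1 is in a HELIX range, residue 2 in a SHEET range; geometry from
    the ideal-geometry dihedral builder, rounded to PDB precision.
    """
    chain = fm.backbone_from_dihedrals(
        [-57.0, -57.0, -57.0], -47.0, 180.0, resnames=["ALA", "GLY", "PRO"]
    )
    lines = [
        "HEADER    SYNTHETIC FIXTURE                       01-JAN-20   XXXX\n",
        f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.\n",
        "HELIX    1   1 ALA A    1  ALA A    1  1                                   1\n",
        "SHEET    1   A 1 GLY A   2  GLY A   2  0\n",
    ]
    serial = 1
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            el = f" {atom.element}" if len(atom.element) == 1 else atom.element
            if atom.name == "CB" and i == 0 and altloc_cb:
                lines.append(
                    _atom_line(serial, "CB", "A", res.resname, "A", res.seqnum,
                               np.round(atom.coord, 3), occ=0.7, element=el)
                )
                serial += 1
                lines.append(
                    _atom_line(serial, "CB", "B", res.resname, "A", res.seqnum,
                               np.round(atom.coord + 0.5, 3), occ=0.3, element=el)
                )
                serial += 1
            else:
                lines.append(
                    _atom_line(serial, atom.name, " ", res.resname, "A", res.seqnum,
                               np.round(atom.coord, 3), element=el)
                )
                serial += 1
        if i == 0 and with_hydrogen:
            lines.append(
                _atom_line(serial, "H", " ", res.resname, "A", res.seqnum,
                           np.round(res.coord("N") + np.array([0, 0, 1.0]), 3),
                           element=" H")
            )
            serial += 1
    lines.append("END\n")
    return "".join(lines)


@pytest.fixture
def tripeptide_pdb(tmp_path):
    p = tmp_path / "tri.pdb"
    p.write_text(make_tripeptide_pdb())
    return p


@pytest.fixture
def tripeptide_pdb_altloc(tmp_path):
    p = tmp_path / "tri_alt.pdb"
    p.write_text(make_tripeptide_pdb(altloc_cb=True))
    return p


@pytest.fixture
def tripeptide_pdb_lowres(tmp_path):
    p = tmp_path / "tri_low.pdb"
    p.write_text(make_tripeptide_pdb(resolution=2.5))
    return p
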