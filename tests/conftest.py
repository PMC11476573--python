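"""Shared fixtures: hand-written minimal PDB text and toy complexes."""

from __future__ import annotations

import numpy as np
import pytest

from ifacekit.structure_model import (
    Atom,
    ResidueKey,
    Structure,
    assign_protonation,
)
from ifacekit.synthetic_data import (
    PlantedContact,
    PlantedHB,
    PlantedSB,
    PlantedSite,
    PlantSpec,
    make_toy_complex,
)

TWO_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       3.630   3.636   1.254  1.00  0.00           C
ATOM      9  O   ALA A   2       3.210   3.061   2.261  1.00  0.00           O
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "two_res.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


def make_atoms(rows):
    """rows: (chain, seq, res_name, atom_name, element, xyz)."""
    pairs = []
    for n, (chain, seq, res, name, element, xyz) in enumerate(rows, start=1):
        pairs.append((
            ResidueKey(chain, seq, "", res),
            Atom(n, name, element, np.array(xyz, dtype=float),
                 is_hydrogen=element.upper() == "H"),
        ))
    return pairs


@pytest.fixture
def two_atom_structure():
    """One atom per group; the pair distance is exactly 3.5 A."""
    def build(distance: float) -> Structure:
        pairs = make_atoms([
            ("A", 1, "ALA", "CB", "C", (0.0, 0.0, 0.0)),
            ("B", 1, "ALA", "CB", "C", (distance, 0.0, 0.0)),
        ])
        return Structure(pairs, {"A": ["A"], "B": ["B"]})
    return build


@pytest.fixture
def random_cloud():
    """Random two-chain point cloud (no planted structure) for oracles."""
    def build(n_per_side: int = 150, seed: int = 0) -> Structure:
        rng = np.random.default_rng(seed)
        rows = []
        for chain, offset in (("A", 0.0), ("B", 4.0)):
            xyz = rng.uniform(0, 20, size=(n_per_side, 3))
            xyz[:, 0] += offset  # overlapping boxes -> plenty of contacts
            for k in range(n_per_side):
                rows.append((chain, 1 + k // 5, "ALA", f"C{k % 5}", "C",
                             xyz[k]))
        return Structure(make_atoms(rows), {"A": ["A"], "B": ["B"]})
    return build


@pytest.fixture
def planted_complex():
    """Toy complex with known HBs, SBs, contacts, sites and glyco residues."""
    spec = PlantSpec(
        hbs=[
            PlantedHB(donor=("SER", 281), acceptor=("ASP", 13),
                      donor_atom="OG", acceptor_atom="OD1",
                      distance=2.9, donor_side="B"),
            PlantedHB(donor=("GLN", 807), acceptor=("CYS", 34),
                      donor_atom="NE2", acceptor_atom="O",
                      distance=2.9, donor_side="B"),
        ],
        sbs=[
            PlantedSB(cation=("LYS", 622), anion=("ASP", 38),
                      cation_atom="NZ", anion_atom="OD1",
                      distance=3.0, cation_side="B"),
        ],
        contacts=[PlantedContact(("ALA", 400), ("ALA", 500), 3.2)],
        sites=[PlantedSite(("TYR", 150), 6.5)],
        seed=42,
    )
    s, ledger = make_toy_complex(spec)
    assign_protonation(s, {})
    return s, ledger
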