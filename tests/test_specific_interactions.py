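"""Hydrogen-bond / salt-bridge detection, precedence and backbone flags."""

import numpy as np
import pytest

from ifacekit.specific_interactions import (
    HBCriteria,
    SpecificInteraction,
    annotate_backbone,
    detect_hydrogen_bonds,
    detect_salt_bridges,
    detect_specific_interactions,
)
from ifacekit.structure_model import (
    ResidueKey,
    Structure,
    assign_protonation,
)
from ifacekit.synthetic_data import (
    PlantedHB,
    PlantedSB,
    PlantSpec,
    make_toy_complex,
)

from conftest import make_atoms


def _pair_structure(rows):
    s = Structure(make_atoms(rows), {"A": ["A"], "B": ["B"]})
    assign_protonation(s, {})
    return s


class TestHydrogenBonds:
    def test_ideal_geometry_detected(self):
        """Ser OG-H...O=C at 2.9 A / 165 degrees is one hydrogen bond."""
        d, a = np.array([0.0, 0.0, 0.0]), np.array([2.9, 0.0, 0.0])
        from ifacekit.synthetic_data import _hydrogen_position
        h = _hydrogen_position(d, a, 165.0)
        s = _pair_structure([
            ("A", 1, "SER", "CB", "C", (-1.4, 0.2, 0.0)),
            ("A", 1, "SER", "OG", "O", tuple(d)),
            ("A", 1, "SER", "HG", "H", tuple(h)),
            ("B", 2, "GLY", "O", "O", tuple(a)),
            ("B", 2, "GLY", "C", "C", (3.9, 0.9, 0.0)),
        ])
        found = detect_hydrogen_bonds(s, HBCriteria(hydrogen_aware=True))
        assert len(found) == 1
        assert found[0].kind == "HB"
        assert found[0].distance == pytest.approx(2.9, abs=1e-6)
        assert found[0].angle == pytest.approx(165.0, abs=0.5)

    def test_bent_geometry_rejected_when_hydrogen_aware(self):
        d, a = np.array([0.0, 0.0, 0.0]), np.array([2.9, 0.0, 0.0])
        from ifacekit.synthetic_data import _hydrogen_position
        h = _hydrogen_position(d, a, 90.0)
        s = _pair_structure([
            ("A", 1, "SER", "OG", "O", tuple(d)),
            ("A", 1, "SER", "HG", "H", tuple(h)),
            ("B", 2, "GLY", "O", "O", tuple(a)),
        ])
        criteria = HBCriteria(dha_angle_min=120.0, hydrogen_aware=True)
        assert detect_hydrogen_bonds(s, criteria) == []

    def test_hydrogen_free_fallback(self):
        """Without hydrogens, the donor-acceptor distance criterion applies
        to typed donor/acceptor atoms only."""
        s = _pair_structure([
            ("A", 13, "ASP", "OD1", "O", (0.0, 0.0, 0.0)),
            ("B", 281, "SER", "OG", "O", (2.8, 0.0, 0.0)),
        ])
        found = detect_hydrogen_bonds(s)
        assert len(found) == 1
        hb = found[0]
        assert (hb.residue_a.label, hb.residue_b.label) == ("Asp13", "Ser281")
        assert hb.backbone_a == "" and hb.backbone_b == ""
        assert hb.notation() == "Asp13-Ser281 (HB)"

    def test_untyped_atoms_do_not_bond(self):
        s = _pair_structure([
            ("A", 1, "ALA", "CB", "C", (0.0, 0.0, 0.0)),
            ("B", 2, "ALA", "CB", "C", (2.8, 0.0, 0.0)),
        ])
        assert detect_hydrogen_bonds(s) == []

    def test_hydrogen_aware_requires_hydrogens(self):
        s = _pair_structure([
            ("A", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
            ("B", 2, "GLY", "O", "O", (2.9, 0.0, 0.0)),
        ])
        with pytest.raises(ValueError, match="without *hydrogens|hydrogens"):
            detect_hydrogen_bonds(s, HBCriteria(hydrogen_aware=True))

    def test_tightening_never_adds(self, planted_complex):
        s, _ = planted_complex
        loose = detect_hydrogen_bonds(s, HBCriteria(donor_acceptor_max=3.5))
        tight = detect_hydrogen_bonds(s, HBCriteria(donor_acceptor_max=3.0))
        assert {i.pair_key() for i in tight} <= {i.pair_key() for i in loose}


class TestSaltBridges:
    def test_lys_glu_pair(self):
        s = _pair_structure([
            ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("B", 2, "GLU", "OE1", "O", (3.0, 0.0, 0.0)),
        ])
        found = detect_salt_bridges(s)
        assert len(found) == 1
        assert found[0].kind == "SB"
        assert found[0].distance == pytest.approx(3.0)

    def test_ser_og_is_not_anionic(self):
        s = _pair_structure([
            ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("B", 2, "SER", "OG", "O", (3.0, 0.0, 0.0)),
        ])
        assert detect_salt_bridges(s) == []

    def test_min_nitrogen_oxygen_distance_reported(self):
        s = _pair_structure([
            ("A", 1, "ARG", "NH1", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "ARG", "NH2", "N", (0.0, 1.9, 0.0)),
            ("B", 2, "ASP", "OD1", "O", (3.2, 0.0, 0.0)),
            ("B", 2, "ASP", "OD2", "O", (3.2, 1.5, 0.0)),
        ])
        found = detect_salt_bridges(s)
        assert len(found) == 1  # one SB per charged-group pair
        expected = np.sqrt((3.2 - 0.0) ** 2 + (1.9 - 1.5) ** 2)
        assert found[0].distance == pytest.approx(min(3.2, expected))

    def test_hip_histidine_is_cationic(self):
        rows = [
            ("A", 1, "HIS", "ND1", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "HIS", "NE2", "N", (1.3, 0.0, 0.0)),
            ("B", 2, "ASP", "OD1", "O", (-3.0, 0.0, 0.0)),
        ]
        s = Structure(make_atoms(rows), {"A": ["A"], "B": ["B"]})
        assign_protonation(s, {s.find_residue("A", 1): "HIP"})
        assert len(detect_salt_bridges(s)) == 1
        assign_protonation(s, {s.find_residue("A", 1): "HIE"})
        assert detect_salt_bridges(s) == []

    def test_planted_sbs_recovered_without_double_count(self):
        """5 planted SBs and 4 planted HBs: each reported exactly once."""
        spec = PlantSpec.random(n_contacts=0, n_hbs=4, n_sbs=5, seed=17)
        s, ledger = make_toy_complex(spec)
        assign_protonation(s, {})
        found = detect_specific_interactions(s)
        assert sorted(i.pair_key() for i in found) == \
            sorted(i.pair_key() for i in ledger.interactions)
        assert sum(1 for i in found if i.kind == "SB") == 5
        assert sum(1 for i in found if i.kind == "HB") == 4

    def test_sb_precedence_over_hb(self):
        """A cationic-anionic N-O pair in both definitions reports as SB."""
        s = _pair_structure([
            ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("B", 2, "GLU", "OE1", "O", (2.9, 0.0, 0.0)),
        ])
        found = detect_specific_interactions(s)
        assert [i.kind for i in found] == ["SB"]


class TestBackboneAnnotation:
    def test_backbone_oxygen_flag(self):
        i = SpecificInteraction(
            "HB", ResidueKey("A", 34, "", "CYS"), ResidueKey("B", 807, "", "GLN"),
            atoms_a=("O",), atoms_b=("NE2",), distance=2.9)
        out = annotate_backbone(i)
        assert (out.backbone_a, out.backbone_b) == ("O", "")
        assert out.notation() == "Cys34^O-Gln807 (HB)"

    def test_sidechain_both_sides(self):
        i = SpecificInteraction(
            "HB", ResidueKey("A", 13, "", "ASP"), ResidueKey("B", 281, "", "SER"),
            atoms_a=("OD1",), atoms_b=("OG",), distance=2.8)
        out = annotate_backbone(i)
        assert (out.backbone_a, out.backbone_b) == ("", "")

    def test_amide_flag(self):
        i = SpecificInteraction(
            "HB", ResidueKey("A", 36, "", "PHE"), ResidueKey("B", 806, "", "GLU"),
            atoms_a=("N",), atoms_b=("OE1",), distance=2.9)
        assert annotate_backbone(i).backbone_a == "HN"

    def test_planted_backbone_hb_detected_with_flag(self, planted_complex):
        """Backbone-O acceptor yields the ^O superscript on that side."""
        s, ledger = planted_complex
        found = detect_specific_interactions(s)
        cys = next(i for i in found if i.residue_a.label == "Cys34")
        assert cys.backbone_a == "O"
        assert cys.backbone_b == ""
        assert cys.notation() == "Cys34^O-Gln807 (HB)"


class TestDeterminism:
    def test_sorted_and_repeatable(self, planted_complex):
        s, _ = planted_complex
        a = detect_specific_interactions(s)
        b = detect_specific_interactions(s)
        assert [i.notation() for i in a] == [i.notation() for i in b]
        keys = [(i.residue_a.sort_key(), i.residue_b.sort_key(), i.kind)
                for i in a]
        assert keys == sorted(keys)


def test_criteria_validation():
    with pytest.raises(ValueError):
        HBCriteria(donor_acceptor_max=-1)
    with pytest.raises(ValueError):
        HBCriteria(dha_angle_min=200.0)
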