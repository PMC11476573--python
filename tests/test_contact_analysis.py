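"""Close-contact enumeration, pose ranking, glyco and site reports."""

import numpy as np
import pytest

from ifacekit.contact_analysis import (
    brute_force_contacts,
    close_contacts,
    functional_site_proximity,
    glycosite_contacts,
    rank_complexes,
)
from ifacekit.structure_model import ResidueKey, Structure, assign_protonation
from ifacekit.synthetic_data import (
    PlantedContact,
    PlantSpec,
    make_toy_complex,
)

from conftest import make_atoms


class TestCloseContacts:
    def test_inclusive_boundary(self, two_atom_structure):
        """'No more than 3.5 A' includes a pair at exactly 3.50 A."""
        cs = close_contacts(two_atom_structure(3.50))
        assert len(cs.pairs) == 1
        assert cs.n_atoms_a == cs.n_atoms_b == 1

    def test_just_outside_cutoff(self, two_atom_structure):
        cs = close_contacts(two_atom_structure(3.51))
        assert len(cs.pairs) == 0
        assert cs.interface_residues_a == []

    def test_matches_independent_double_loop(self, random_cloud):
        """KD-tree search equals a plain double loop on a 300-atom cloud."""
        s = random_cloud(150, seed=3)
        cs = close_contacts(s, cutoff=3.5)
        idx_a = s.group_atom_indices("A")
        idx_b = s.group_atom_indices("B")
        expected = set()
        for i in idx_a:
            for j in idx_b:
                if np.sqrt(((s.coords[i] - s.coords[j]) ** 2).sum()) <= 3.5:
                    expected.add((int(i), int(j)))
        assert {(i, j) for i, j, _ in cs.pairs} == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_kdtree_equals_brute_force(self, random_cloud, seed):
        s = random_cloud(100, seed=seed)
        assert close_contacts(s).pairs == brute_force_contacts(s).pairs

    @pytest.mark.parametrize("seed", [0, 4])
    def test_cutoff_monotonicity(self, random_cloud, seed):
        """Pairs at a tighter cutoff are a subset of those at a looser one."""
        s = random_cloud(100, seed=seed)
        sets = [
            {(i, j) for i, j, _ in close_contacts(s, c).pairs}
            for c in (2.5, 3.0, 3.5, 4.5)
        ]
        for tighter, looser in zip(sets, sets[1:]):
            assert tighter <= looser

    def test_group_swap_symmetry(self, planted_complex):
        s, _ = planted_complex
        cs = close_contacts(s, groups=("A", "B"))
        sw = close_contacts(s, groups=("B", "A"))
        assert cs.n_atoms_a == sw.n_atoms_b
        assert cs.n_atoms_b == sw.n_atoms_a
        assert cs.interface_residues_a == sw.interface_residues_b
        assert {(i, j) for i, j, _ in cs.pairs} == \
            {(j, i) for i, j, _ in sw.pairs}

    def test_hydrogens_excluded_by_default(self):
        rows = [
            ("A", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
            ("A", 1, "SER", "HG", "H", (1.0, 0.0, 0.0)),
            ("B", 1, "ALA", "CB", "C", (3.4, 0.0, 0.0)),
        ]
        s = Structure(make_atoms(rows), {"A": ["A"], "B": ["B"]})
        assert len(close_contacts(s).pairs) == 1  # OG-CB only
        assert len(close_contacts(s, include_hydrogens=True).pairs) == 2

    def test_single_group_rejected(self, two_residue_pdb):
        from ifacekit.structure_model import load_structure
        s = load_structure(two_residue_pdb, {"A": ["A"]})
        with pytest.raises(ValueError, match="two groups"):
            close_contacts(s)

    def test_invalid_cutoff(self, two_atom_structure):
        with pytest.raises(ValueError, match="positive"):
            close_contacts(two_atom_structure(3.0), cutoff=0.0)


class TestRanking:
    COUNTS = {
        1: (372, 396), 2: (319, 287), 3: (278, 267), 4: (540, 543),
        5: (347, 327), 6: (472, 432), 7: (447, 444), 8: (362, 390),
        9: (351, 352), 10: (267, 231),
    }

    def test_min_side_reproduces_published_order(self):
        """The min-side score ranks the docked poses 4 > 7 > 6."""
        report = rank_complexes(self.COUNTS)
        assert report.top == 4
        assert report.order[:3] == [4, 7, 6]

    def test_alternative_scores_selectable(self):
        by_sum = rank_complexes(self.COUNTS, score="sum")
        assert by_sum.top == 4
        assert by_sum.order[:3] == [4, 6, 7]  # sum prefers 6 over 7

    def test_input_order_irrelevant(self):
        shuffled = dict(reversed(list(self.COUNTS.items())))
        assert rank_complexes(shuffled).order == \
            rank_complexes(self.COUNTS).order

    def test_single_entry(self):
        assert rank_complexes({"only": (10, 12)}).order == ["only"]

    def test_deterministic_tie_break(self):
        report = rank_complexes({"b": (5, 9), "a": (5, 7), "c": (9, 5)})
        assert report.order == ["a", "b", "c"]  # equal min-side: id order

    def test_mixed_cutoffs_rejected(self, two_atom_structure):
        cs1 = close_contacts(two_atom_structure(3.0), cutoff=3.5)
        cs2 = close_contacts(two_atom_structure(3.0), cutoff=4.0)
        with pytest.raises(ValueError, match="mixed"):
            rank_complexes({"a": cs1, "b": cs2})

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no complexes"):
            rank_complexes({})


class TestGlycositeContacts:
    def _glyco_complex(self):
        contacts = [PlantedContact(("ALA", i), ("ALA", 100 + i), 3.2)
                    for i in range(1, 18)]
        contacts += [
            PlantedContact(("ALA", 50), ("ASN", 685), 3.1),
            PlantedContact(("ALA", 51), ("ASN", 913), 3.0),
            PlantedContact(("ALA", 52), ("ASN", 480), 3.3, via_glycan=True),
        ]
        spec = PlantSpec(
            contacts=contacts,
            glyco_residues=[("ASN", 685), ("ASN", 913), ("ASN", 480)],
            seed=5)
        return make_toy_complex(spec)

    def test_planted_glyco_contacts_flagged(self):
        """3 of 20 planted contacts touch listed Asn (one via its glycan)."""
        s, ledger = self._glyco_complex()
        cs = close_contacts(s)
        assert len(cs.pairs) == 20
        gc = glycosite_contacts(cs, ledger.glyco_residues)
        assert len(gc.pairs) == 3
        flagged = {s.residue_of_atom(j).res_seq for _, j, _ in gc.pairs}
        assert flagged == {685, 913, 480}

    def test_glycan_atoms_inherit_anchor_residue(self):
        s, _ = self._glyco_complex()
        nag = next(k for k in s.residues if k.res_name == "NAG")
        assert s.glycan_parents[nag].res_name == "ASN"
        assert s.glycan_parents[nag].res_seq == 480

    def test_empty_glyco_list(self, planted_complex):
        s, _ = planted_complex
        cs = close_contacts(s)
        assert glycosite_contacts(cs, []).pairs == []

    def test_specific_interaction_flagging(self, planted_complex):
        s, ledger = planted_complex
        cs = close_contacts(s)
        listed = [ledger.interactions[0].residue_b]
        gc = glycosite_contacts(cs, listed, interactions=ledger.interactions)
        assert ledger.interactions[0].residue_b in gc.in_specific_interaction


class TestFunctionalSites:
    def test_constructed_distance_ladder(self):
        """Sites planted at 3.2 / 6.5 / 12 / 30 A categorize as expected."""
        from ifacekit.synthetic_data import PlantedSite
        spec = PlantSpec(
            sites=[
                PlantedSite(("CYS", 34), 3.2),
                PlantedSite(("TYR", 150), 6.5),
                PlantedSite(("TYR", 411), 12.0),
                PlantedSite(("LYS", 525), 30.0),
            ],
            seed=2)
        s, ledger = make_toy_complex(spec)
        sites = [k for k, _, _ in ledger.sites]
        reports = functional_site_proximity(s, sites)
        got = {r.site_residue.label: (r.category,
                                      round(r.min_distance_to_partner, 2))
               for r in reports}
        assert got["Cys34"] == ("contacting", 3.2)
        assert got["Tyr150"] == ("proximal", 6.5)
        assert got["Tyr411"] == ("distal", 12.0)
        assert got["Lys525"] == ("distal", 30.0)

    def test_absent_site_is_an_error(self, planted_complex):
        s, _ = planted_complex
        with pytest.raises(KeyError):
            functional_site_proximity(s, [ResidueKey("A", 9999, "", "CYS")])
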