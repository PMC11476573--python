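"""Hydrogen-bond and salt-bridge detection with backbone annotation.

Detection is purely geometric. When the structure carries hydrogens the
hydrogen-aware criterion (donor-acceptor distance, hydrogen-acceptor
distance and D-H...A angle) applies; otherwise a hydrogen-free fallback uses
the donor-acceptor distance alone, restricted to atoms that are typed as
donors or acceptors given the residue type and its protonation tag.

Salt bridges are charged-group nitrogen-oxygen pairs: Lys NZ, Arg NE/NH1/NH2,
doubly protonated His and free N-termini on the cationic side; Asp OD1/OD2,
Glu OE1/OE2 and free C-termini on the anionic side. A pair satisfying both
definitions is reported once, as a salt bridge.

Backbone participation is annotated the way interface tables in the
structural literature superscript it: ``O`` when the backbone carbonyl
oxygen takes part, ``HN`` when the backbone amide does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .structure_model import ResidueKey, Structure

__all__ = [
    "SpecificInteraction",
    "HBCriteria",
    "detect_hydrogen_bonds",
    "detect_salt_bridges",
    "detect_specific_interactions",
    "annotate_backbone",
]

# --- donor / acceptor typing ------------------------------------------------

#: side-chain N/O donor atoms (heavy atom carrying at least one polar H)
SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "TRP": ("NE1",),
}

#: side-chain N/O acceptor atoms
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
}

#: histidine ring nitrogens: (protonated=donor, deprotonated=acceptor)
HIS_RING = {"HID": ("ND1", "NE2"), "HIE": ("NE2", "ND1")}

CATIONIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
ANIONIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

#: covalent D-H search radius, Angstrom
_H_BOND_RADIUS = 1.3


@dataclass
class HBCriteria:
    """Geometric hydrogen-bond definition.

    donor_acceptor_max : heavy-atom D...A ceiling, Angstrom (default 3.5)
    hydrogen_acceptor_max : H...A ceiling in hydrogen-aware mode (default 2.5)
    dha_angle_min : minimum D-H...A angle, degrees (default 120)
    hydrogen_aware : True / False / None (None = auto-detect from structure)
    """

    donor_acceptor_max: float = 3.5
    hydrogen_acceptor_max: float = 2.5
    dha_angle_min: float = 120.0
    hydrogen_aware: bool | None = None

    def __post_init__(self) -> None:
        if min(self.donor_acceptor_max, self.hydrogen_acceptor_max) <= 0:
            raise ValueError("distance criteria must be positive")
        if not (0.0 < self.dha_angle_min <= 180.0):
            raise ValueError("dha_angle_min must be in (0, 180]")


@dataclass
class SpecificInteraction:
    """One hydrogen bond or salt bridge between the two analysis groups."""

    kind: str  # "HB" | "SB"
    residue_a: ResidueKey
    residue_b: ResidueKey
    atoms_a: tuple[str, ...]
    atoms_b: tuple[str, ...]
    backbone_a: str = ""  # "", "O", "HN" or "O,HN"
    backbone_b: str = ""
    distance: float = float("nan")
    angle: float | None = None

    def pair_key(self) -> tuple:
        return (
            self.residue_a.chain_id, self.residue_a.res_seq,
            self.residue_a.insertion_code,
            self.residue_b.chain_id, self.residue_b.res_seq,
            self.residue_b.insertion_code, self.kind,
        )

    def involves(self, key: ResidueKey) -> bool:
        def short(k: ResidueKey) -> tuple:
            return (k.chain_id, k.res_seq, k.insertion_code)
        return short(key) in (short(self.residue_a), short(self.residue_b))

    def notation(self) -> str:
        """Literature-style label, e.g. ``Asp38-Lys622 (SB)`` or
        ``Cys34^O-Gln807 (HB)``."""
        def side(res: ResidueKey, flags: str) -> str:
            sup = f"^{flags}" if flags else ""
            return f"{res.label}{sup}"
        return (f"{side(self.residue_a, self.backbone_a)}-"
                f"{side(self.residue_b, self.backbone_b)} ({self.kind})")


# --- helpers ----------------------------------------------------------------


def _sorted_unique(interactions: Iterable[SpecificInteraction]) -> list[SpecificInteraction]:
    return sorted(
        interactions,
        key=lambda i: (i.residue_a.sort_key(), i.residue_b.sort_key(), i.kind))


def _donor_atoms(s: Structure, key: ResidueKey) -> list[int]:
    """Atom indices that can donate an H bond, given residue type and tag."""
    out = []
    names = SIDECHAIN_DONORS.get(key.res_name, ())
    if key.res_name == "HIS":
        state = s.protonation.get(key, "HIE")
        if state == "HIP":
            names = ("ND1", "NE2")
        else:
            names = (HIS_RING.get(state, HIS_RING["HIE"])[0],)
    for i in s.residues[key]:
        a = s.atoms[i]
        if a.name in names:
            out.append(i)
        elif a.name == "N" and key.res_name != "PRO":
            out.append(i)  # backbone amide
    return out


def _acceptor_atoms(s: Structure, key: ResidueKey) -> list[int]:
    out = []
    names = SIDECHAIN_ACCEPTORS.get(key.res_name, ())
    if key.res_name == "HIS":
        state = s.protonation.get(key, "HIE")
        names = () if state == "HIP" else (HIS_RING.get(state, HIS_RING["HIE"])[1],)
    for i in s.residues[key]:
        a = s.atoms[i]
        if a.name in names or a.name in ("O", "OXT"):
            out.append(i)
    return out


def _attached_hydrogens(s: Structure, donor_idx: int) -> list[int]:
    key = s._atom_residue[donor_idx]
    out = []
    for i in s.residues[key]:
        a = s.atoms[i]
        if a.is_hydrogen and np.linalg.norm(
                s.coords[i] - s.coords[donor_idx]) <= _H_BOND_RADIUS:
            out.append(i)
    return out


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1, v2 = d - h, a - h
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _has_hydrogens(s: Structure) -> bool:
    return any(a.is_hydrogen for a in s.atoms)


def _backbone_flag(atom_names: Sequence[str]) -> str:
    flags = []
    if any(n in ("O", "OXT") for n in atom_names):
        flags.append("O")
    if any(n in ("N", "H", "HN", "H1", "H2", "H3") for n in atom_names):
        flags.append("HN")
    return ",".join(flags)


def annotate_backbone(i: SpecificInteraction) -> SpecificInteraction:
    """Set per-side backbone flags from the participating atom names."""
    return replace(
        i,
        backbone_a=_backbone_flag(i.atoms_a),
        backbone_b=_backbone_flag(i.atoms_b),
    )


def _two_groups(s: Structure) -> tuple[str, str]:
    names = sorted(s.groups)
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    return names[0], names[1]


# --- hydrogen bonds ---------------------------------------------------------


def detect_hydrogen_bonds(
    s: Structure,
    criteria: HBCriteria | None = None,
    groups: tuple[str, str] | None = None,
) -> list[SpecificInteraction]:
    """Inter-group hydrogen bonds under the configured geometric criteria.

    Multiple atom-level geometries between one residue pair collapse to a
    single record keeping the shortest donor-acceptor distance; backbone
    flags accumulate over all contributing geometries.
    """
    criteria = criteria or HBCriteria()
    ga, gb = groups or _two_groups(s)
    aware = criteria.hydrogen_aware
    if aware is None:
        aware = _has_hydrogens(s)
    elif aware and not _has_hydrogens(s):
        raise ValueError(
            "hydrogen-aware criteria requested on a structure without "
            "hydrogens")

    best: dict[tuple, SpecificInteraction] = {}
    flags: dict[tuple, tuple[set[str], set[str]]] = {}
    for res_d in s.residues:
        if not s.is_polymer_residue(res_d):
            continue
        for di in _donor_atoms(s, res_d):
            gd = s.group_of_atom(di)
            for res_a in s.residues:
                if not s.is_polymer_residue(res_a):
                    continue
                ga2 = s.group_of_chain(res_a.chain_id)
                if ga2 == gd:
                    continue
                for ai in _acceptor_atoms(s, res_a):
                    d_da = float(np.linalg.norm(s.coords[di] - s.coords[ai]))
                    if d_da > criteria.donor_acceptor_max:
                        continue
                    angle = None
                    if aware:
                        ok = False
                        for hi in _attached_hydrogens(s, di):
                            d_ha = float(np.linalg.norm(
                                s.coords[hi] - s.coords[ai]))
                            ang = _dha_angle(
                                s.coords[di], s.coords[hi], s.coords[ai])
                            if (d_ha <= criteria.hydrogen_acceptor_max
                                    and ang >= criteria.dha_angle_min):
                                ok, angle = True, ang
                                break
                        if not ok:
                            continue
                    # orient the record as (group A residue, group B residue)
                    if gd == ga:
                        rec = SpecificInteraction(
                            "HB", res_d, res_a,
                            (s.atoms[di].name,), (s.atoms[ai].name,),
                            distance=d_da, angle=angle)
                    else:
                        rec = SpecificInteraction(
                            "HB", res_a, res_d,
                            (s.atoms[ai].name,), (s.atoms[di].name,),
                            distance=d_da, angle=angle)
                    key = rec.pair_key()
                    fa, fb = flags.setdefault(key, (set(), set()))
                    fa.update(rec.atoms_a)
                    fb.update(rec.atoms_b)
                    if key not in best or d_da < best[key].distance:
                        best[key] = rec

    out = []
    for key, rec in best.items():
        fa, fb = flags[key]
        rec = replace(
            rec,
            backbone_a=_backbone_flag(sorted(fa)),
            backbone_b=_backbone_flag(sorted(fb)),
        )
        out.append(rec)
    return _sorted_unique(out)


# --- salt bridges -----------------------------------------------------------


def _cationic_groups(s: Structure) -> list[tuple[ResidueKey, list[int]]]:
    out = []
    for key in s.residues:
        if not s.is_polymer_residue(key):
            continue
        names: tuple[str, ...] = CATIONIC_ATOMS.get(key.res_name, ())
        if key.res_name == "HIS" and s.protonation.get(key) == "HIP":
            names = ("ND1", "NE2")
        idx = [i for i in s.residues[key] if s.atoms[i].name in names]
        if idx:
            out.append((key, idx))
    # free N-termini
    for chain_id in s.free_termini:
        poly = s.polymer_residues(chain_id)
        if poly:
            first = poly[0]
            idx = [i for i in s.residues[first] if s.atoms[i].name == "N"]
            if idx:
                out.append((first, idx))
    return out


def _anionic_groups(s: Structure) -> list[tuple[ResidueKey, list[int]]]:
    out = []
    for key in s.residues:
        if not s.is_polymer_residue(key):
            continue
        names = ANIONIC_ATOMS.get(key.res_name, ())
        idx = [i for i in s.residues[key] if s.atoms[i].name in names]
        if idx:
            out.append((key, idx))
    for chain_id in s.free_termini:
        poly = s.polymer_residues(chain_id)
        if poly:
            last = poly[-1]
            idx = [i for i in s.residues[last]
                   if s.atoms[i].name in ("O", "OXT")]
            if idx:
                out.append((last, idx))
    return out


def detect_salt_bridges(
    s: Structure,
    max_distance: float = 4.0,
    groups: tuple[str, str] | None = None,
) -> list[SpecificInteraction]:
    """One salt bridge per (cationic group, anionic group) pair whose minimum
    nitrogen-oxygen distance is within ``max_distance``."""
    ga, gb = groups or _two_groups(s)
    out: dict[tuple, SpecificInteraction] = {}
    for ckey, cidx in _cationic_groups(s):
        cgroup = s.group_of_chain(ckey.chain_id)
        for akey, aidx in _anionic_groups(s):
            if s.group_of_chain(akey.chain_id) == cgroup:
                continue
            dmat = np.linalg.norm(
                s.coords[cidx][:, None, :] - s.coords[aidx][None, :, :],
                axis=-1)
            dmin = float(dmat.min())
            if dmin > max_distance:
                continue
            ci, aj = np.unravel_index(int(np.argmin(dmat)), dmat.shape)
            catom, aatom = s.atoms[cidx[ci]].name, s.atoms[aidx[aj]].name
            if cgroup == ga:
                rec = SpecificInteraction(
                    "SB", ckey, akey, (catom,), (aatom,), distance=dmin)
            else:
                rec = SpecificInteraction(
                    "SB", akey, ckey, (aatom,), (catom,), distance=dmin)
            rec = annotate_backbone(rec)
            key = rec.pair_key()
            if key not in out or dmin < out[key].distance:
                out[key] = rec
    return _sorted_unique(out.values())


# --- combined detection with SB precedence ----------------------------------


def detect_specific_interactions(
    s: Structure,
    hb_criteria: HBCriteria | None = None,
    sb_max_distance: float = 4.0,
    groups: tuple[str, str] | None = None,
) -> list[SpecificInteraction]:
    """Hydrogen bonds plus salt bridges with the precedence rule applied.

    A cationic-anionic nitrogen-oxygen atom pair that satisfies both
    definitions is reported once, as a salt bridge.
    """
    sbs = detect_salt_bridges(s, sb_max_distance, groups=groups)
    hbs = detect_hydrogen_bonds(s, hb_criteria, groups=groups)
    sb_atom_pairs = set()
    for sb in sbs:
        rp = (sb.residue_a.sort_key(), sb.residue_b.sort_key())
        for an in sb.atoms_a:
            for bn in sb.atoms_b:
                sb_atom_pairs.add((rp, an, bn))
        # the full charged-group atom set shadows equivalent HB geometries
        for an in CATIONIC_ATOMS.get(sb.residue_a.res_name, ()) + \
                ANIONIC_ATOMS.get(sb.residue_a.res_name, ()):
            for bn in CATIONIC_ATOMS.get(sb.residue_b.res_name, ()) + \
                    ANIONIC_ATOMS.get(sb.residue_b.res_name, ()):
                sb_atom_pairs.add((rp, an, bn))
    kept = []
    for hb in hbs:
        rp = (hb.residue_a.sort_key(), hb.residue_b.sort_key())
        shadowed = all(
            (rp, an, bn) in sb_atom_pairs
            for an in hb.atoms_a for bn in hb.atoms_b
        ) and any((rp, an, bn) in sb_atom_pairs
                  for an in hb.atoms_a for bn in hb.atoms_b)
        if not shadowed:
            kept.append(hb)
    return _sorted_unique(kept + sbs)
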