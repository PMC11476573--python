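"""Seeded toy complexes and trajectories with machine-readable ground truth.

Real docked protein-protein poses are rarely redistributable, so every
pipeline stage is exercised on constructed two-chain complexes instead: each
requested steric contact, hydrogen bond or salt bridge is *planted* at an
exact target distance (and, optionally, D-H...A angle) on its own interface
slot, with every other atom kept far enough away that nothing undeclared is
detectable. The ledger returned alongside the structure lists exactly what
was planted, which is what the recovery tests assert against.

Residues use a reduced atom set: the four backbone atoms plus side-chain
pseudo-atoms carrying real PDB names (enough for every detector's atom-name
logic, with no rotamer realism). Author numbering is free, so fixtures can
echo literature labels such as Asp38 or Lys622.

Trajectories realize a per-interaction presence schedule exactly: in
"present" frames the planted geometry is restored (with sub-0.02 A jitter,
well inside detection margins); in "absent" frames the partner residue is
displaced 8 A away, exceeding every criterion by >= 1.5 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .specific_interactions import SpecificInteraction, annotate_backbone
from .structure_model import Atom, ResidueKey, Structure, is_backbone_name
from .trajectory_analysis import Trajectory

__all__ = [
    "PlantedContact",
    "PlantedHB",
    "PlantedSB",
    "PlantedSite",
    "PlantSpec",
    "ScheduleSpec",
    "ToyLedger",
    "make_toy_complex",
    "make_synthetic_trajectory",
]

# side chains extend along +y; successive atoms >= 1.2 A apart in y,
# secondary branch atoms >= 0.9 A below their tip and >= 1.1 A lateral
BACKBONE_TEMPLATE = [
    ("N", (-1.35, -0.45, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (1.30, -0.45, 0.0)),
    ("O", (1.40, -1.65, 0.0)),
]

SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", (0.0, 1.5, 0.0))],
    "SER": [("CB", (0.0, 1.5, 0.0)), ("OG", (0.0, 2.75, 0.0))],
    "THR": [("CB", (0.0, 1.5, 0.0)), ("OG1", (0.0, 2.75, 0.0)),
            ("CG2", (1.15, 1.85, 0.0))],
    "CYS": [("CB", (0.0, 1.5, 0.0)), ("SG", (0.0, 2.9, 0.0))],
    "VAL": [("CB", (0.0, 1.5, 0.0)), ("CG1", (0.0, 2.75, 0.0)),
            ("CG2", (1.15, 1.85, 0.0))],
    "LEU": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("CD1", (0.0, 4.0, 0.0)), ("CD2", (1.15, 3.1, 0.0))],
    "ILE": [("CB", (0.0, 1.5, 0.0)), ("CG1", (0.0, 2.75, 0.0)),
            ("CD1", (0.0, 4.0, 0.0))],
    "PHE": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("CZ", (0.0, 4.5, 0.0))],
    "ASP": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("OD1", (0.0, 4.0, 0.0)), ("OD2", (1.15, 3.1, 0.0))],
    "ASN": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("OD1", (0.0, 4.0, 0.0)), ("ND2", (1.15, 3.1, 0.0))],
    "GLU": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("CD", (0.0, 4.0, 0.0)), ("OE1", (0.0, 5.25, 0.0)),
            ("OE2", (1.15, 4.35, 0.0))],
    "GLN": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("CD", (0.0, 4.0, 0.0)), ("OE1", (0.0, 5.25, 0.0)),
            ("NE2", (1.15, 4.35, 0.0))],
    "LYS": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("CD", (0.0, 4.0, 0.0)), ("CE", (0.0, 5.25, 0.0)),
            ("NZ", (0.0, 6.45, 0.0))],
    "ARG": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("CD", (0.0, 4.0, 0.0)), ("NE", (0.0, 5.2, 0.0)),
            ("CZ", (0.0, 6.4, 0.0)), ("NH1", (0.95, 7.25, 0.0)),
            ("NH2", (-0.95, 7.25, 0.0))],
    "HIS": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("ND1", (1.1, 3.55, 0.0)), ("CD2", (-1.1, 3.55, 0.0)),
            ("CE1", (0.7, 4.85, 0.0)), ("NE2", (-0.7, 4.85, 0.0))],
    "TYR": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("CZ", (0.0, 4.75, 0.0)), ("OH", (0.0, 6.0, 0.0))],
    "MET": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("SD", (0.0, 4.15, 0.0)), ("CE", (0.0, 5.5, 0.0))],
    "TRP": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.75, 0.0)),
            ("NE1", (1.1, 3.7, 0.0)), ("CZ2", (0.0, 5.2, 0.0))],
    "PRO": [("CB", (0.0, 1.5, 0.0)), ("CG", (0.0, 2.6, 0.0)),
            ("CD", (-1.2, 1.7, 0.0))],
}

#: reduced N-acetylglucosamine stub: C1 is the attachment carbon
NAG_TEMPLATE = [
    ("C1", (0.0, 0.0, 0.0)),
    ("C2", (1.2, -0.6, 0.0)),
    ("O5", (-1.2, -0.6, 0.0)),
    ("O3", (0.0, -1.35, 0.0)),
]

_ELEMENT = {"N": "N", "C": "C", "O": "O", "S": "S", "H": "H"}


def _element_of(name: str) -> str:
    return _ELEMENT.get(name[0], name[0])


# --- plant specifications ---------------------------------------------------

ResSpec = tuple[str, int]  # (three-letter name, author seq number)


@dataclass(frozen=True)
class PlantedContact:
    """A steric close contact between one atom on each chain."""

    a: ResSpec
    b: ResSpec
    distance: float = 3.2
    a_atom: str = "CB"
    b_atom: str = "CB"
    via_glycan: bool = False  # contact through a NAG stub attached to b


@dataclass(frozen=True)
class PlantedHB:
    """A hydrogen bond; ``angle`` plants an explicit hydrogen on the donor."""

    donor: ResSpec
    acceptor: ResSpec
    donor_atom: str
    acceptor_atom: str
    distance: float = 2.9
    angle: float | None = None
    donor_side: str = "A"


@dataclass(frozen=True)
class PlantedSB:
    cation: ResSpec
    anion: ResSpec
    cation_atom: str = "NZ"
    anion_atom: str = "OD1"
    distance: float = 3.0
    cation_side: str = "B"


@dataclass(frozen=True)
class PlantedSite:
    """A functional-site residue on chain A at an exact minimum distance to
    the partner chain (realized with a dedicated probe residue)."""

    residue: ResSpec
    distance: float
    probe: ResSpec = ("ALA", 999)
    probe_atom: str = "CB"
    site_atom: str | None = None  # default: side-chain tip


@dataclass
class PlantSpec:
    """Full recipe for one toy complex; the seed fully determines output."""

    contacts: Sequence[PlantedContact] = ()
    hbs: Sequence[PlantedHB] = ()
    sbs: Sequence[PlantedSB] = ()
    sites: Sequence[PlantedSite] = ()
    glyco_residues: Sequence[ResSpec] = ()
    n_fillers: tuple[int, int] = (4, 4)
    chain_separation: float = 30.0
    slot_spacing: float = 12.0
    site_spacing: float = 60.0
    seed: int = 0
    chains: tuple[str, str] = ("A", "B")
    group_names: tuple[str, str] = ("A", "B")
    free_termini: tuple[str, ...] = ()

    @classmethod
    def random(
        cls,
        n_contacts: int = 5,
        n_hbs: int = 3,
        n_sbs: int = 3,
        seed: int = 0,
        **kwargs,
    ) -> "PlantSpec":
        """Assorted random plants with construction margins respected."""
        rng = np.random.default_rng(seed)
        seq = iter(range(10, 10_000))
        contacts = [
            PlantedContact(("ALA", next(seq)), ("ALA", next(seq)),
                           distance=float(rng.uniform(2.9, 3.3)))
            for _ in range(n_contacts)
        ]
        donors = [("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
                  ("ASN", "ND2"), ("GLN", "NE2")]
        acceptors = [("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"),
                     ("THR", "OG1")]
        hbs = []
        for _ in range(n_hbs):
            dres, datom = donors[int(rng.integers(len(donors)))]
            ares, aatom = acceptors[int(rng.integers(len(acceptors)))]
            hbs.append(PlantedHB(
                (dres, next(seq)), (ares, next(seq)), datom, aatom,
                distance=float(rng.uniform(2.7, 3.1)),
                donor_side="A" if rng.random() < 0.5 else "B"))
        cations = [("LYS", "NZ"), ("ARG", "NH1")]
        anions = [("ASP", "OD1"), ("GLU", "OE1")]
        sbs = []
        for _ in range(n_sbs):
            cres, catom = cations[int(rng.integers(len(cations)))]
            ares, aatom = anions[int(rng.integers(len(anions)))]
            sbs.append(PlantedSB(
                (cres, next(seq)), (ares, next(seq)), catom, aatom,
                distance=float(rng.uniform(2.8, 3.4)),
                cation_side="A" if rng.random() < 0.5 else "B"))
        return cls(contacts=contacts, hbs=hbs, sbs=sbs, seed=seed, **kwargs)


@dataclass
class ScheduleSpec:
    """Per-interaction presence schedule for a synthetic trajectory.

    ``fractions`` maps a ledger interaction (by pair key, or by index into
    ``ToyLedger.interactions``) to its presence fraction; unlisted planted
    interactions stay present in every frame. ``frames_present`` is realized
    as ``round(fraction * n_frames)`` exactly.
    """

    fractions: Mapping[object, float]
    n_frames: int = 100
    jitter_sigma: float = 0.05
    seed: int = 0


# --- ground-truth ledger ----------------------------------------------------


@dataclass
class ToyLedger:
    """Machine-readable record of everything planted in a toy complex."""

    interactions: list[SpecificInteraction] = field(default_factory=list)
    #: (residue A, residue B, atom A, atom B, distance, via_glycan) for every
    #: planted heavy-atom pair expected inside the 3.5 A contact cutoff
    contact_pairs: list[tuple[ResidueKey, ResidueKey, str, str, float, bool]] = \
        field(default_factory=list)
    sites: list[tuple[ResidueKey, float, str]] = field(default_factory=list)
    glyco_residues: list[ResidueKey] = field(default_factory=list)

    def hbs(self) -> list[SpecificInteraction]:
        return [i for i in self.interactions if i.kind == "HB"]

    def sbs(self) -> list[SpecificInteraction]:
        return [i for i in self.interactions if i.kind == "SB"]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("record\tdetail\n")
            for i in self.interactions:
                fh.write(f"interaction\t{i.notation()}\t{i.distance:.3f}\n")
            for a, b, an, bn, d, glyco in self.contact_pairs:
                fh.write(
                    f"contact\t{a.label}:{an}-{b.label}:{bn}\t{d:.3f}"
                    f"\t{'glyco' if glyco else ''}\n")
            for key, d, cat in self.sites:
                fh.write(f"site\t{key.label}\t{d:.3f}\t{cat}\n")
            for key in self.glyco_residues:
                fh.write(f"glyco_residue\t{key.label}\n")


# --- construction -----------------------------------------------------------


class _Builder:
    def __init__(self, spec: PlantSpec) -> None:
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.pairs: list[tuple[ResidueKey, Atom]] = []
        self.serial = 0
        self.used: dict[str, set[int]] = {c: set() for c in spec.chains}
        self.placed_atoms: dict[tuple[str, int, str], np.ndarray] = {}

    def residue_offsets(
        self, res_name: str, chain_pos: str, facing_atom: str,
    ) -> list[tuple[str, np.ndarray]]:
        """Template offsets oriented so ``facing_atom`` points at the interface.

        Chain A residues face +y, chain B residues face -y. A backbone
        facing atom flips the residue so the backbone, not the side chain,
        fronts the interface.
        """
        sidechain = list(SIDECHAIN_TEMPLATES[res_name])
        # the facing atom must be the geometric tip toward the interface;
        # if another side-chain atom extends further, exchange their offsets
        names = [n for n, _ in sidechain]
        if facing_atom in names and sidechain:
            tip_i = max(range(len(sidechain)), key=lambda i: sidechain[i][1][1])
            face_i = names.index(facing_atom)
            if face_i != tip_i:
                (na, oa), (nt, ot) = sidechain[face_i], sidechain[tip_i]
                sidechain[face_i], sidechain[tip_i] = (na, ot), (nt, oa)
            # retract every other atom until it clears the nearest possible
            # partner position (tip + 2.7 A) by > 3.65 A, so only the planted
            # pair can ever satisfy a criterion
            fx, fy, _fz = sidechain[face_i][1]
            for k, (name, (x, y, z)) in enumerate(sidechain):
                if k == face_i:
                    continue
                dx2 = (x - fx) ** 2
                need = np.sqrt(max(3.65 ** 2 - dx2, 0.0)) - 2.7
                if fy - y < need:
                    sidechain[k] = (name, (x, fy - need, z))
        template = BACKBONE_TEMPLATE + sidechain
        flip_for_backbone = is_backbone_name(facing_atom)
        sign = 1.0 if chain_pos == "A" else -1.0
        if flip_for_backbone:
            sign = -sign
        return [(name, np.array([dx, sign * dy, dz]))
                for name, (dx, dy, dz) in template]

    def add_residue(
        self,
        chain_id: str,
        res: ResSpec,
        ca_position: np.ndarray,
        offsets: list[tuple[str, np.ndarray]],
        altloc: str = "",
    ) -> ResidueKey:
        res_name, res_seq = res
        if res_seq in self.used[chain_id]:
            raise ValueError(
                f"infeasible spec: residue {chain_id}/{res_seq} planted twice")
        self.used[chain_id].add(res_seq)
        key = ResidueKey(chain_id, res_seq, "", res_name)
        for name, off in offsets:
            self.serial += 1
            pos = ca_position + off
            self.pairs.append((key, Atom(
                serial=self.serial, name=name, element=_element_of(name),
                coords=pos, is_hydrogen=name.startswith("H"),
                is_backbone=is_backbone_name(name), altloc=altloc)))
            self.placed_atoms[(chain_id, res_seq, name)] = pos
        return key

    def add_hydrogen(self, key: ResidueKey, name: str, pos: np.ndarray) -> None:
        self.serial += 1
        self.pairs.append((key, Atom(
            serial=self.serial, name=name, element="H", coords=pos,
            is_hydrogen=True, is_backbone=is_backbone_name(name))))


def _offset_of(offsets: list[tuple[str, np.ndarray]], atom: str) -> np.ndarray:
    for name, off in offsets:
        if name == atom:
            return off
    raise ValueError(f"atom {atom!r} not in reduced template")


def _hydrogen_position(
    donor: np.ndarray, acceptor: np.ndarray, dha_angle: float,
    bond: float = 1.0,
) -> np.ndarray:
    """Place H at ``bond`` A from the donor realizing the D-H...A angle."""
    axis = acceptor - donor
    d = float(np.linalg.norm(axis))
    axis = axis / d
    # any perpendicular in-plane direction
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(axis, [1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)

    def angle_at_h(phi: float) -> float:
        h = donor + bond * (np.cos(phi) * axis + np.sin(phi) * perp)
        v1, v2 = donor - h, acceptor - h
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.degrees(np.arccos(np.clip(c, -1, 1))))

    lo, hi = 0.0, np.pi * 0.75  # angle_at_h is monotone decreasing in phi
    target = float(dha_angle)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if angle_at_h(mid) > target:
            lo = mid
        else:
            hi = mid
    phi = 0.5 * (lo + hi)
    return donor + bond * (np.cos(phi) * axis + np.sin(phi) * perp)


def make_toy_complex(spec: PlantSpec) -> tuple[Structure, ToyLedger]:
    """Build a two-chain complex realizing every planted item exactly.

    Each planted pair occupies its own interface slot along x (12 A apart by
    default); functional-site plants go to widely separated slots so their
    minimum partner distance is exactly the planted one. Filler residues sit
    across a 30 A gap and never approach any criterion.
    """
    chain_a, chain_b = spec.chains
    b = _Builder(spec)
    ledger = ToyLedger()
    slot = 0

    def slot_x() -> float:
        nonlocal slot
        x = slot * spec.slot_spacing
        slot += 1
        return x

    def plant_pair(
        res_a: ResSpec, atom_a: str, res_b: ResSpec, atom_b: str,
        distance: float,
    ) -> tuple[ResidueKey, ResidueKey]:
        x = slot_x()
        offs_a = b.residue_offsets(res_a[0], "A", atom_a)
        key_a = b.add_residue(chain_a, res_a, np.array([x, 0.0, 0.0]), offs_a)
        pa = b.placed_atoms[(chain_a, res_a[1], atom_a)]
        offs_b = b.residue_offsets(res_b[0], "B", atom_b)
        pb = pa + np.array([0.0, distance, 0.0])
        ca_b = pb - _offset_of(offs_b, atom_b)
        key_b = b.add_residue(chain_b, res_b, ca_b, offs_b)
        return key_a, key_b

    # steric contacts -------------------------------------------------------
    for pc in spec.contacts:
        if pc.via_glycan:
            x = slot_x()
            offs_a = b.residue_offsets(pc.a[0], "A", pc.a_atom)
            key_a = b.add_residue(chain_a, pc.a, np.array([x, 0.0, 0.0]), offs_a)
            pa = b.placed_atoms[(chain_a, pc.a[1], pc.a_atom)]
            # NAG O3 meets the contact; C1 bonds to the Asn ND2 above it
            o3 = pa + np.array([0.0, pc.distance, 0.0])
            nag_ca = o3 - np.array([0.0, -1.35, 0.0])
            nag_key = b.add_residue(
                chain_b, ("NAG", 5000 + pc.b[1]), nag_ca,
                [(n, np.array(off)) for n, off in NAG_TEMPLATE])
            c1 = b.placed_atoms[(chain_b, 5000 + pc.b[1], "C1")]
            offs_b = b.residue_offsets(pc.b[0], "B", "ND2")
            nd2 = c1 + np.array([0.0, 1.45, 0.0])
            ca_b = nd2 - _offset_of(offs_b, "ND2")
            key_b = b.add_residue(chain_b, pc.b, ca_b, offs_b)
            ledger.contact_pairs.append(
                (key_a, key_b, pc.a_atom, "O3", pc.distance, True))
            continue
        key_a, key_b = plant_pair(
            pc.a, pc.a_atom, pc.b, pc.b_atom, pc.distance)
        if pc.distance <= 3.5:
            ledger.contact_pairs.append(
                (key_a, key_b, pc.a_atom, pc.b_atom, pc.distance, False))

    # hydrogen bonds --------------------------------------------------------
    for hb in spec.hbs:
        if hb.donor_side == "A":
            key_d, key_acc = plant_pair(
                hb.donor, hb.donor_atom, hb.acceptor, hb.acceptor_atom,
                hb.distance)
            key_a, key_b = key_d, key_acc
            atoms_a, atoms_b = (hb.donor_atom,), (hb.acceptor_atom,)
        else:
            key_acc, key_d = plant_pair(
                hb.acceptor, hb.acceptor_atom, hb.donor, hb.donor_atom,
                hb.distance)
            key_a, key_b = key_acc, key_d
            atoms_a, atoms_b = (hb.acceptor_atom,), (hb.donor_atom,)
        if hb.angle is not None:
            donor_pos = b.placed_atoms[(
                key_d.chain_id, key_d.res_seq, hb.donor_atom)]
            acc_pos = b.placed_atoms[(
                key_acc.chain_id, key_acc.res_seq, hb.acceptor_atom)]
            hpos = _hydrogen_position(donor_pos, acc_pos, hb.angle)
            b.add_hydrogen(key_d, "H" + hb.donor_atom[1:] or "H", hpos)
        rec = annotate_backbone(SpecificInteraction(
            "HB", key_a, key_b, atoms_a, atoms_b,
            distance=hb.distance, angle=hb.angle))
        ledger.interactions.append(rec)
        if hb.distance <= 3.5:
            ledger.contact_pairs.append(
                (key_a, key_b, atoms_a[0], atoms_b[0], hb.distance, False))

    # salt bridges ----------------------------------------------------------
    for sb in spec.sbs:
        if sb.cation_side == "A":
            key_c, key_an = plant_pair(
                sb.cation, sb.cation_atom, sb.anion, sb.anion_atom,
                sb.distance)
            key_a, key_b = key_c, key_an
            atoms_a, atoms_b = (sb.cation_atom,), (sb.anion_atom,)
        else:
            key_an, key_c = plant_pair(
                sb.anion, sb.anion_atom, sb.cation, sb.cation_atom,
                sb.distance)
            key_a, key_b = key_an, key_c
            atoms_a, atoms_b = (sb.anion_atom,), (sb.cation_atom,)
        rec = annotate_backbone(SpecificInteraction(
            "SB", key_a, key_b, atoms_a, atoms_b, distance=sb.distance))
        ledger.interactions.append(rec)
        if sb.distance <= 3.5:
            ledger.contact_pairs.append(
                (key_a, key_b, atoms_a[0], atoms_b[0], sb.distance, False))

    # functional sites ------------------------------------------------------
    site_base = max(slot, 1) * spec.slot_spacing + spec.site_spacing
    for n, site in enumerate(spec.sites):
        x = site_base + n * spec.site_spacing
        res_name = site.residue[0]
        tip = site.site_atom or (
            SIDECHAIN_TEMPLATES[res_name][-1][0]
            if SIDECHAIN_TEMPLATES[res_name] else "CA")
        # HIS/ASP-like templates: the geometric tip is the deepest y atom
        offs = b.residue_offsets(res_name, "A", tip)
        deepest = max(offs, key=lambda t: t[1][1])
        tip = site.site_atom or deepest[0]
        key_site = b.add_residue(
            chain_a, site.residue, np.array([x, 0.0, 0.0]), offs)
        ptip = b.placed_atoms[(chain_a, site.residue[1], tip)]
        offs_b = b.residue_offsets(site.probe[0], "B", site.probe_atom)
        pb = ptip + np.array([0.0, site.distance, 0.0])
        ca_b = pb - _offset_of(offs_b, site.probe_atom)
        probe_name, probe_seq = site.probe
        while probe_seq in b.used[chain_b]:
            probe_seq += 1
        b.add_residue(chain_b, (probe_name, probe_seq), ca_b, offs_b)
        category = ("contacting" if site.distance <= 3.5
                    else "proximal" if site.distance <= 8.0 else "distal")
        ledger.sites.append((key_site, site.distance, category))

    # fillers ---------------------------------------------------------------
    filler_a, filler_b = spec.n_fillers
    jitter = b.rng.normal(0.0, 0.1, size=(filler_a + filler_b, 3))
    next_seq_a = next_seq_b = 1

    def fresh(chain: str, start: int) -> int:
        while start in b.used[chain]:
            start += 1
        return start

    for k in range(filler_a):
        x = slot_x()
        next_seq_a = fresh(chain_a, next_seq_a)
        b.add_residue(
            chain_a, ("GLY", next_seq_a),
            np.array([x, 0.0, 0.0]) + jitter[k],
            b.residue_offsets("GLY", "A", "CB"))
        next_seq_a += 1
    for k in range(filler_b):
        x = slot_x()
        next_seq_b = fresh(chain_b, next_seq_b)
        b.add_residue(
            chain_b, ("ALA", next_seq_b),
            np.array([x, spec.chain_separation, 0.0]) + jitter[filler_a + k],
            b.residue_offsets("ALA", "B", "CB"))
        next_seq_b += 1

    ga, gb = spec.group_names
    structure = Structure(
        b.pairs, {ga: (chain_a,), gb: (chain_b,)},
        free_termini=spec.free_termini,
        name=f"toy-seed{spec.seed}")
    structure.assign_glycan_parents()
    ledger.glyco_residues = [
        ResidueKey(chain_b, seq, "", name) for name, seq in spec.glyco_residues]
    return structure, ledger


# --- trajectories -----------------------------------------------------------


def make_synthetic_trajectory(
    structure: Structure,
    ledger: ToyLedger,
    schedule: ScheduleSpec,
) -> tuple[Trajectory, dict[tuple, list[int]]]:
    """Realize a presence schedule over a toy complex.

    Returns the trajectory and the per-frame truth: for every scheduled
    interaction, the sorted list of frame indices in which it is present.
    ``round(fraction * n_frames)`` frames are present, exactly.
    """
    if schedule.n_frames < 1:
        raise ValueError("need at least one frame")
    keys = [i.pair_key() for i in ledger.interactions]
    fractions: dict[tuple, float] = {}
    for ref, frac in schedule.fractions.items():
        if isinstance(ref, int):
            key = keys[ref]
        elif ref in keys:
            key = ref
        else:
            raise KeyError(f"schedule references unknown interaction {ref!r}")
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"fraction {frac} outside [0, 1]")
        fractions[key] = float(frac)

    rng = np.random.default_rng(schedule.seed)
    n = schedule.n_frames
    truth: dict[tuple, list[int]] = {}
    present: dict[tuple, set[int]] = {}
    for key in keys:
        frac = fractions.get(key, 1.0)
        k = int(round(frac * n))
        idx = sorted(int(i) for i in rng.permutation(n)[:k])
        truth[key] = idx
        present[key] = set(idx)

    base = structure.coords.copy()
    pin_sigma = min(schedule.jitter_sigma, 0.02)
    by_key = {i.pair_key(): i for i in ledger.interactions}
    res_atoms = {
        k: (structure.residues[by_key[k].residue_a],
            structure.residues[by_key[k].residue_b])
        for k in keys
    }
    pinned = sorted({
        i for idxs in res_atoms.values() for side in idxs for i in side})
    # residues of planted contacts / sites stay pinned too
    for a, bkey, *_ in ledger.contact_pairs:
        for key in (a, bkey):
            if key in structure.residues:
                pinned.extend(structure.residues[key])
    pinned = np.array(sorted(set(pinned)), dtype=int)

    frames = np.empty((n, len(structure.atoms), 3), dtype=float)
    away = np.array([0.0, 8.0, 0.0])
    for f in range(n):
        coords = base + rng.normal(0.0, schedule.jitter_sigma, base.shape)
        coords[pinned] = base[pinned] + rng.normal(
            0.0, pin_sigma, (len(pinned), 3))
        for key in keys:
            if f in present[key]:
                continue
            _, b_idx = res_atoms[key]
            coords[b_idx] = base[b_idx] + away + rng.normal(
                0.0, pin_sigma, (len(b_idx), 3))
        frames[f] = coords
    return Trajectory(structure, frames), truth
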