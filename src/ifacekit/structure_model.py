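"""Atomic structure model: parsing, protonation bookkeeping and formal charges.

The unit of all geometric analysis is a :class:`Structure` whose chains are
partitioned into exactly two *analysis groups* (e.g. ``"HSA"`` vs ``"ACE"``).
Structures are read from PDB or mmCIF through gemmi; author residue
numbering (with insertion codes) is the canonical label space, so residue
labels such as Cys34 or Lys622 match the crystallographic literature.

The model never builds hydrogens or repairs missing atoms; structures may
arrive hydrogen-free and every downstream geometric criterion has a
hydrogen-free fallback.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ResidueKey",
    "Structure",
    "ChargeReport",
    "load_structure",
    "assign_protonation",
    "net_formal_charge",
    "parse_residue_label",
    "AMINO3",
    "THREE_TO_ONE",
]

# --- residue vocabulary -----------------------------------------------------

AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: common N-linked glycan residue names (zero formal charge)
GLYCAN_RESNAMES = {"NAG", "NDG", "BMA", "MAN", "FUC", "GAL", "GLC", "SIA", "XYS"}

WATER_RESNAMES = {"HOH", "WAT", "DOD"}

#: default formal charges of hetero entities; anything else is a hard error
DEFAULT_HETERO_CHARGES = {
    "ZN": 2, "NA": 1, "K": 1, "MG": 2, "CA": 2, "CL": -1,
    **{name: 0 for name in GLYCAN_RESNAMES},
    **{name: 0 for name in WATER_RESNAMES},
}

#: side-chain formal charge at pH 7 (His handled via protonation tag)
SIDECHAIN_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

HIS_STATES = ("HID", "HIE", "HIP", "default")

BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}
BACKBONE_HYDROGENS = {"H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"}


def is_backbone_name(name: str) -> bool:
    """Backbone membership is derivable from the PDB atom name alone."""
    return name in BACKBONE_HEAVY or name in BACKBONE_HYDROGENS


def _infer_element(name: str, res_name: str) -> str:
    """Standard PDB name -> element inference for four-column atom names."""
    stripped = name.strip()
    if not stripped:
        return ""
    if res_name.upper() in DEFAULT_HETERO_CHARGES and stripped.upper() in (
        "ZN", "NA", "K", "MG", "CA", "CL",
    ):
        return stripped.capitalize()
    first = stripped[0]
    if first.isdigit():  # e.g. 1H, 2HB
        return "H"
    return first.upper()


@dataclass(frozen=True)
class ResidueKey:
    """Author-numbered residue identity: (chain, seq, insertion code, name)."""

    chain_id: str
    res_seq: int
    insertion_code: str = ""
    res_name: str = ""

    def sort_key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def label(self) -> str:
        """Title-case literature label, e.g. ``Cys34`` or ``Lys622A``."""
        return f"{self.res_name.capitalize()}{self.res_seq}{self.insertion_code}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chain_id}/{self.label}"


def parse_residue_label(label: str, chain_id: str) -> ResidueKey:
    """Parse a ``Cys34``-style label into a :class:`ResidueKey`."""
    name = label[:3].upper()
    rest = label[3:]
    icode = ""
    if rest and rest[-1].isalpha():
        icode, rest = rest[-1], rest[:-1]
    return ResidueKey(chain_id, int(rest), icode, name)


@dataclass
class Atom:
    """One atom; ``coords`` is a length-3 view into the owning structure."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False
    is_backbone: bool = False
    altloc: str = ""
    occupancy: float = 1.0
    index: int = -1  # position in Structure.coords; set by Structure


@dataclass
class ChargeReport:
    """Formal-charge bookkeeping and counterion requirement."""

    per_residue_charges: dict[ResidueKey, int]
    net_charge: int
    counterions_needed: int
    counterion_species: str

    @staticmethod
    def counterions_for(net_charge: int, species: str = "NA") -> int:
        ion_charge = {"NA": 1, "K": 1, "CL": -1}.get(species.upper())
        if ion_charge is None:
            raise ValueError(f"unknown counterion species {species!r}")
        if net_charge * ion_charge < 0:
            return abs(net_charge)
        return 0


class Structure:
    """Atoms grouped by residue, with chains partitioned into analysis groups.

    Parameters
    ----------
    atoms :
        Ordered ``(ResidueKey, Atom)`` pairs; atoms of one residue must be
        contiguous.
    groups :
        Mapping of group name -> set of chain ids. Every chain present must
        be assigned to exactly one group.
    free_termini :
        Chain ids whose polypeptide termini carry the free +1/-1 charges.
    hetero_charges :
        Formal charge per hetero residue name, extending the defaults.
    """

    def __init__(
        self,
        atoms: Sequence[tuple[ResidueKey, Atom]],
        groups: Mapping[str, Iterable[str]],
        free_termini: Iterable[str] = (),
        hetero_charges: Mapping[str, int] | None = None,
        name: str = "",
    ) -> None:
        if not atoms:
            raise ValueError("structure has zero atoms")
        self.name = name
        self.groups: dict[str, frozenset[str]] = {
            g: frozenset(chains) for g, chains in groups.items()
        }
        chain_to_group: dict[str, str] = {}
        for g, chains in self.groups.items():
            for c in chains:
                if c in chain_to_group:
                    raise ValueError(f"chain {c!r} assigned to two groups")
                chain_to_group[c] = g
        self._chain_to_group = chain_to_group
        self.free_termini = frozenset(free_termini)
        self.hetero_charges = dict(DEFAULT_HETERO_CHARGES)
        if hetero_charges:
            self.hetero_charges.update(
                {k.upper(): v for k, v in hetero_charges.items()})

        self.atoms: list[Atom] = []
        self.residues: dict[ResidueKey, list[int]] = {}
        coords = np.empty((len(atoms), 3), dtype=float)
        for i, (key, atom) in enumerate(atoms):
            if key.chain_id not in chain_to_group:
                raise ValueError(
                    f"chain {key.chain_id!r} not covered by group_spec")
            coords[i] = np.asarray(atom.coords, dtype=float)
            atom.index = i
            self.atoms.append(atom)
            self.residues.setdefault(key, []).append(i)
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        self.coords = coords
        for atom in self.atoms:  # views: set_coords updates atoms in place
            atom.coords = self.coords[atom.index]

        self._atom_residue: list[ResidueKey] = [None] * len(self.atoms)  # type: ignore
        for key, idxs in self.residues.items():
            for i in idxs:
                self._atom_residue[i] = key
        self.protonation: dict[ResidueKey, str] = {}
        #: glycan residue -> protein attachment residue (for annotation)
        self.glycan_parents: dict[ResidueKey, ResidueKey] = {}
        #: full construct (SEQRES) length per chain when the file declares
        #: one; modeled residue counts come from polymer_residues()
        self.seqres_lengths: dict[str, int] = {}

    # -- identity helpers ---------------------------------------------------

    def group_of_chain(self, chain_id: str) -> str:
        return self._chain_to_group[chain_id]

    def group_of_atom(self, index: int) -> str:
        return self._chain_to_group[self._atom_residue[index].chain_id]

    def residue_of_atom(self, index: int) -> ResidueKey:
        key = self._atom_residue[index]
        return self.glycan_parents.get(key, key)

    def group_atom_indices(self, group: str, include_hydrogens: bool = True) -> np.ndarray:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        idx = [
            a.index for a in self.atoms
            if self.group_of_atom(a.index) == group
            and (include_hydrogens or not a.is_hydrogen)
        ]
        return np.asarray(idx, dtype=int)

    def find_residue(self, chain_id: str, res_seq: int, insertion_code: str = "") -> ResidueKey:
        for key in self.residues:
            if (key.chain_id, key.res_seq, key.insertion_code) == (
                    chain_id, res_seq, insertion_code):
                return key
        raise KeyError(f"residue {chain_id}/{res_seq}{insertion_code} absent")

    def residue_atoms(self, key: ResidueKey) -> list[Atom]:
        return [self.atoms[i] for i in self.residues[key]]

    def atom_in_residue(self, key: ResidueKey, name: str) -> Atom:
        for atom in self.residue_atoms(key):
            if atom.name == name:
                return atom
        raise KeyError(f"atom {name!r} not in {key}")

    def is_polymer_residue(self, key: ResidueKey) -> bool:
        return key.res_name in AMINO3

    def polymer_residues(self, chain_id: str | None = None) -> list[ResidueKey]:
        keys = [k for k in self.residues if self.is_polymer_residue(k)]
        if chain_id is not None:
            keys = [k for k in keys if k.chain_id == chain_id]
        return sorted(keys, key=ResidueKey.sort_key)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for key in self.residues:
            seen.setdefault(key.chain_id, None)
        return list(seen)

    # -- coordinates --------------------------------------------------------

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError("coordinate shape mismatch")
        self.coords[:] = coords

    # -- group extraction (charge additivity, per-side analyses) ------------

    def subset_by_group(self, group: str) -> "Structure":
        chains = self.groups[group]
        pairs = [
            (self._atom_residue[a.index], _copy_atom(a))
            for a in self.atoms
            if self._atom_residue[a.index].chain_id in chains
        ]
        sub = Structure(
            pairs, {group: chains},
            free_termini=self.free_termini & chains,
            hetero_charges=self.hetero_charges,
            name=f"{self.name}:{group}",
        )
        sub.protonation = {
            k: v for k, v in self.protonation.items() if k.chain_id in chains}
        sub.glycan_parents = {
            k: v for k, v in self.glycan_parents.items() if k.chain_id in chains}
        return sub

    # -- glycan attachment ---------------------------------------------------

    def assign_glycan_parents(self, max_bond: float = 1.8) -> None:
        """Attach sugar residues to their anchor Asn (or parent sugar).

        Glycan atoms inherit the residue identity of the attachment Asn for
        annotation purposes; chained sugars resolve through their parent.
        """
        sugars = [k for k in self.residues if k.res_name in GLYCAN_RESNAMES]
        anchors = {
            k: self.residues[k] for k in self.residues
            if k.res_name == "ASN" or k in self.glycan_parents
        }
        resolved: dict[ResidueKey, ResidueKey] = dict(self.glycan_parents)
        pending = list(sugars)
        for _ in range(len(pending) + 1):
            still = []
            for sugar in pending:
                best: tuple[float, ResidueKey] | None = None
                s_idx = self.residues[sugar]
                for cand in list(anchors) + [
                        s for s in resolved if s != sugar]:
                    if cand == sugar:
                        continue
                    c_idx = self.residues[cand]
                    d = np.linalg.norm(
                        self.coords[s_idx][:, None, :] - self.coords[c_idx][None, :, :],
                        axis=-1).min()
                    if d <= max_bond and (best is None or d < best[0]):
                        best = (d, cand)
                if best is None:
                    still.append(sugar)
                else:
                    parent = best[1]
                    resolved[sugar] = resolved.get(parent, parent)
            if not still:
                break
            pending = still
        self.glycan_parents = resolved

    # -- I/O -----------------------------------------------------------------

    def to_gemmi(self, coords: np.ndarray | None = None) -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = self.name or "ifacekit"
        model = gemmi.Model("1")
        xyz = self.coords if coords is None else np.asarray(coords, float)
        chains: dict[str, gemmi.Chain] = {}
        for key in sorted(self.residues, key=ResidueKey.sort_key):
            chain = chains.get(key.chain_id)
            if chain is None:
                chain = gemmi.Chain(key.chain_id)
                chains[key.chain_id] = chain
            res = gemmi.Residue()
            res.name = key.res_name
            res.seqid = gemmi.SeqId(key.res_seq, key.insertion_code or " ")
            res.het_flag = "A" if key.res_name in AMINO3 else "H"
            for i in self.residues[key]:
                a = self.atoms[i]
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or "X")
                ga.pos = gemmi.Position(*xyz[i])
                ga.occ = a.occupancy
                ga.altloc = a.altloc.strip() and a.altloc or "\0"
                res.add_atom(ga)
            chain.add_residue(res)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st

    def write_pdb(self, path: str | Path, frames: Sequence[np.ndarray] | None = None) -> None:
        """Write a (multi-model) fixed-column PDB fixture via gemmi."""
        if frames is None:
            self.to_gemmi().write_pdb(str(path))
            return
        st = self.to_gemmi(frames[0])
        for n, frame in enumerate(frames[1:], start=2):
            extra = self.to_gemmi(frame)
            model = extra[0].clone()
            model.num = n
            st.add_model(model)
        st.write_pdb(str(path))


def _copy_atom(a: Atom) -> Atom:
    new = dataclasses.replace(a)
    new.coords = np.array(a.coords, dtype=float)
    new.index = -1
    return new


# --- loading ----------------------------------------------------------------


def load_structure(
    path: str | Path,
    group_spec: Mapping[str, Iterable[str]],
    fmt: str | None = None,
    free_termini: Iterable[str] = (),
    hetero_charges: Mapping[str, int] | None = None,
    keep_waters: bool = True,
    model_index: int = 0,
) -> Structure:
    """Load a PDB or mmCIF file into a grouped :class:`Structure`.

    Chains not named in ``group_spec`` are rejected with an error rather than
    silently dropped; pass an explicit partition covering every retained
    chain. Alternate locations keep the highest-occupancy conformer (ties
    break to the lexicographically first altloc id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st = gemmi.cif.read(str(path))  # type: ignore[assignment]
        st = gemmi.make_structure_from_block(st.sole_block())
    else:
        st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[model_index]

    assigned_chains = {c for chains in group_spec.values() for c in chains}
    pairs: list[tuple[ResidueKey, Atom]] = []
    serial = 0
    for chain in model:
        if chain.name not in assigned_chains:
            raise ValueError(
                f"chain {chain.name!r} present in {path.name} but not in "
                f"group_spec; assign or remove it")
        for res in chain:
            if not keep_waters and res.name in WATER_RESNAMES:
                continue
            key = ResidueKey(
                chain.name, res.seqid.num,
                (res.seqid.icode or "").strip(), res.name.upper())
            for atom in _select_altloc(res):
                serial += 1
                name = atom.name
                element = atom.element.name if atom.element else ""
                if not element or element == "X":
                    element = _infer_element(name, res.name)
                pairs.append((key, Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    is_hydrogen=(element.upper() in ("H", "D")),
                    is_backbone=is_backbone_name(name),
                    altloc=(atom.altloc or "").strip("\0").strip(),
                    occupancy=atom.occ,
                )))
    missing = assigned_chains - {k.chain_id for k, _ in pairs}
    if missing:
        raise ValueError(f"chains named in group_spec absent from file: {sorted(missing)}")
    if not pairs:
        raise ValueError(f"zero atoms after filtering in {path}")
    out = Structure(
        pairs, group_spec, free_termini=free_termini,
        hetero_charges=hetero_charges, name=path.stem)
    for entity in st.entities:
        if entity.entity_type.name != "Polymer" or not entity.full_sequence:
            continue
        for chain in model:
            if any(sub in entity.subchains
                   for sub in {r.subchain for r in chain}):
                out.seqres_lengths[chain.name] = len(entity.full_sequence)
    return out


def _select_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties to first altloc id."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    selected = []
    for name, atoms in by_name.items():
        if len(atoms) == 1:
            selected.append(atoms[0])
        else:
            selected.append(
                max(atoms, key=lambda a: (a.occ, -ord((a.altloc or "A")[0] or "A"))))
    return selected


# --- protonation ------------------------------------------------------------


def assign_protonation(
    s: Structure,
    overrides: Mapping[ResidueKey, str] | None = None,
    default_his: str = "HIE",
    allow_non_his: bool = False,
) -> Structure:
    """Tag histidine protonation states (HID / HIE / HIP) on a structure.

    Tags only affect charge accounting and hydrogen-bond donor/acceptor
    typing, never coordinates. Unlisted histidines get ``default_his``.
    Overrides on non-histidine residues are a contract violation unless
    ``allow_non_his`` is set.
    """
    if default_his not in HIS_STATES:
        raise ValueError(f"unknown default histidine state {default_his!r}")
    overrides = dict(overrides or {})
    tags: dict[ResidueKey, str] = {}
    for key, state in overrides.items():
        if key not in s.residues:
            raise KeyError(f"protonation override on missing residue {key}")
        if state not in HIS_STATES:
            raise ValueError(f"unknown protonation state {state!r} for {key}")
        if key.res_name != "HIS" and not allow_non_his:
            raise ValueError(
                f"protonation override on non-histidine {key} "
                "(pass allow_non_his=True to force)")
        tags[key] = state
    for key in s.residues:
        if key.res_name == "HIS" and key not in tags:
            tags[key] = default_his
    s.protonation = tags
    return s


# --- formal charges ---------------------------------------------------------


def net_formal_charge(s: Structure, counterion_species: str = "NA") -> ChargeReport:
    """Sum per-residue formal charges at pH 7 and size the counterion bath.

    Asp/Glu -1; Lys/Arg +1; His 0 in HID/HIE and +1 in HIP; free N-/C-termini
    +1/-1 per polypeptide chain flagged in ``free_termini``; hetero entities
    per the configured charge table (unknown names are a hard error).
    """
    charges: dict[ResidueKey, int] = {}
    for key in s.residues:
        if s.is_polymer_residue(key):
            if key.res_name == "HIS":
                state = s.protonation.get(key)
                if state is None:
                    raise ValueError(
                        f"histidine {key} has no protonation tag; call "
                        "assign_protonation first")
                charge = 1 if state == "HIP" else 0
            else:
                charge = SIDECHAIN_CHARGE.get(key.res_name, 0)
        else:
            name = key.res_name.upper()
            if name not in s.hetero_charges:
                raise ValueError(
                    f"hetero entity {name!r} has no configured charge")
            charge = s.hetero_charges[name]
        charges[key] = charge

    for chain_id in s.free_termini:
        poly = s.polymer_residues(chain_id)
        if not poly:
            continue
        charges[poly[0]] = charges.get(poly[0], 0) + 1
        charges[poly[-1]] = charges.get(poly[-1], 0) - 1

    net = int(sum(charges.values()))
    return ChargeReport(
        per_residue_charges=charges,
        net_charge=net,
        counterions_needed=ChargeReport.counterions_for(net, counterion_species),
        counterion_species=counterion_species.upper(),
    )
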