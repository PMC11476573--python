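"""Bundled reference data and domain constants for the HSA-ACE system.

The TSVs under ``ifacekit/data`` transcribe the published interface
characterization of the candidate HSA-ACE complexes: per-side
interacting-atom counts of the ten docked poses, and the specific
inter-protein interactions of the three MD-simulated leaders with their
lifetimes over a 100 ns run. They serve as ranking / persistence inputs and
as templates for synthetic trajectories.
"""

from __future__ import annotations

from importlib import resources
from typing import NamedTuple

from .specific_interactions import SpecificInteraction
from .structure_model import ResidueKey, parse_residue_label
from .trajectory_analysis import OccupancyRecord

__all__ = [
    "load_docked_contact_counts",
    "load_md_lifetimes",
    "lifetimes_as_records",
    "ACE_GLYCOSYLATED_ASN",
    "HSA_FUNCTIONAL_SITES",
    "HSA_DOMAINS",
    "HSA_MUTATIONS",
    "ACE_HIS_HID",
]

#: asparagines of ACE carrying N-linked glycans in the cryo-EM structure
ACE_GLYCOSYLATED_ASN = (45, 117, 131, 289, 416, 480, 648, 666, 685, 913, 1162)

#: albumin residues with known functional roles: the free-thiol redox site,
#: the Sudlow I / II catalytic tyrosines and the main glycation site
HSA_FUNCTIONAL_SITES = ("Cys34", "Tyr150", "Tyr411", "Lys525")

#: conventional albumin domain boundaries (author numbering)
HSA_DOMAINS = {"DI": (1, 195), "DII": (196, 383), "DIII": (384, 585)}

#: literature point mutations of albumin relevant to the ACE interface
HSA_MUTATIONS = ("Asp13Asn", "Glu82Lys", "Arg114Gly",
                 "Glu505Lys", "Glu565Lys", "Lys573Glu")

#: ACE histidines assigned the Nd-protonated (HID) form during system
#: preparation; every other histidine defaults to HIE
ACE_HIS_HID = (164, 361, 365, 958, 986, 1018)


#: preferred side-chain donor atom for each donor-capable residue
_DONOR_ATOM = {"SER": "OG", "THR": "OG1", "TYR": "OH", "ASN": "ND2",
               "GLN": "NE2", "LYS": "NZ", "ARG": "NH1", "HIS": "NE2",
               "TRP": "NE1"}
#: preferred side-chain acceptor atom
_ACCEPTOR_ATOM = {"ASP": "OD1", "GLU": "OE1", "ASN": "OD1", "GLN": "OE1",
                  "SER": "OG", "THR": "OG1", "TYR": "OH", "HIS": "ND1"}
_CATION_ATOM = {"LYS": "NZ", "ARG": "NH1"}
_ANION_ATOM = {"ASP": "OD1", "GLU": "OE1"}


def lifetime_plant(
    complex_id: int,
    chains: tuple[str, str] = ("A", "B"),
    group_names: tuple[str, str] = ("A", "B"),
    seed: int = 0,
):
    """Synthetic stand-in for an undeposited MD-simulated complex.

    Builds a :class:`~ifacekit.synthetic_data.PlantSpec` echoing every
    published interaction row of the given complex (same residue names,
    numbers, kinds and backbone participation), plus the per-row presence
    fractions for a synthetic trajectory. Because the toy geometry places
    each planted pair on its own interface slot, a residue appearing in two
    published rows is duplicated under a bumped author number; an
    interaction printed as a backbone-amide salt bridge on a residue that is
    not the chain's first (no free amine) is planted as the hydrogen bond
    the geometric rules would call it.

    Returns ``(spec, fractions)`` with ``fractions`` keyed by the ledger
    interaction index, suitable for
    :class:`~ifacekit.synthetic_data.ScheduleSpec`.
    """
    from .synthetic_data import (
        PlantedHB,
        PlantedSB,
        PlantedSite,
        PlantSpec,
    )

    entries = load_md_lifetimes()[complex_id]
    chain_a, chain_b = chains
    used: dict[str, set[int]] = {chain_a: set(), chain_b: set()}

    def place(chain: str, name: str, seq: int) -> tuple[str, int]:
        while seq in used[chain]:
            seq += 1000
        used[chain].add(seq)
        return (name, seq)

    hbs: list[PlantedHB] = []
    sbs: list[PlantedSB] = []
    hb_frac: list[float] = []
    sb_frac: list[float] = []
    needs_free_nterm = False
    for e in entries:
        ka = parse_residue_label(e.residue_a, chain_a)
        kb = parse_residue_label(e.residue_b, chain_b)
        frac = e.lifetime_percent / 100.0
        kind = e.kind
        if kind == "SB" and e.backbone_a == "HN" and ka.res_seq != 1:
            kind = "HB"  # no free amine: the geometric rules see an HB
        if kind == "SB":
            if e.backbone_a == "HN":  # N-terminal amine as the cation
                needs_free_nterm = True
                sbs.append(PlantedSB(
                    cation=place(chain_a, ka.res_name, ka.res_seq),
                    anion=place(chain_b, kb.res_name, kb.res_seq),
                    cation_atom="N", anion_atom=_ANION_ATOM[kb.res_name],
                    distance=3.0, cation_side="A"))
            elif ka.res_name in _CATION_ATOM:
                sbs.append(PlantedSB(
                    cation=place(chain_a, ka.res_name, ka.res_seq),
                    anion=place(chain_b, kb.res_name, kb.res_seq),
                    cation_atom=_CATION_ATOM[ka.res_name],
                    anion_atom=_ANION_ATOM[kb.res_name],
                    distance=3.0, cation_side="A"))
            else:
                sbs.append(PlantedSB(
                    cation=place(chain_b, kb.res_name, kb.res_seq),
                    anion=place(chain_a, ka.res_name, ka.res_seq),
                    cation_atom=_CATION_ATOM[kb.res_name],
                    anion_atom=_ANION_ATOM[ka.res_name],
                    distance=3.0, cation_side="B"))
            sb_frac.append(frac)
            continue
        # hydrogen bonds: backbone flags fix the geometry; otherwise the
        # first side with a typed donor donates to the other's acceptor
        if e.backbone_a == "O":
            hbs.append(PlantedHB(
                donor=place(chain_b, kb.res_name, kb.res_seq),
                acceptor=place(chain_a, ka.res_name, ka.res_seq),
                donor_atom=_DONOR_ATOM[kb.res_name], acceptor_atom="O",
                distance=2.9, donor_side="B"))
        elif e.backbone_b == "O":
            hbs.append(PlantedHB(
                donor=place(chain_a, ka.res_name, ka.res_seq),
                acceptor=place(chain_b, kb.res_name, kb.res_seq),
                donor_atom=_DONOR_ATOM[ka.res_name], acceptor_atom="O",
                distance=2.9, donor_side="A"))
        elif e.backbone_a == "HN" or (
                e.backbone_a == "" and ka.res_name not in _DONOR_ATOM
                and kb.res_name not in _ACCEPTOR_ATOM):
            hbs.append(PlantedHB(
                donor=place(chain_a, ka.res_name, ka.res_seq),
                acceptor=place(chain_b, kb.res_name, kb.res_seq),
                donor_atom="N", acceptor_atom=_ACCEPTOR_ATOM[kb.res_name],
                distance=2.9, donor_side="A"))
        elif e.backbone_b == "HN":
            hbs.append(PlantedHB(
                donor=place(chain_b, kb.res_name, kb.res_seq),
                acceptor=place(chain_a, ka.res_name, ka.res_seq),
                donor_atom="N", acceptor_atom=_ACCEPTOR_ATOM[ka.res_name],
                distance=2.9, donor_side="B"))
        elif (ka.res_name in _DONOR_ATOM
                and kb.res_name in _ACCEPTOR_ATOM):
            hbs.append(PlantedHB(
                donor=place(chain_a, ka.res_name, ka.res_seq),
                acceptor=place(chain_b, kb.res_name, kb.res_seq),
                donor_atom=_DONOR_ATOM[ka.res_name],
                acceptor_atom=_ACCEPTOR_ATOM[kb.res_name],
                distance=2.9, donor_side="A"))
        else:
            hbs.append(PlantedHB(
                donor=place(chain_b, kb.res_name, kb.res_seq),
                acceptor=place(chain_a, ka.res_name, ka.res_seq),
                donor_atom=_DONOR_ATOM[kb.res_name],
                acceptor_atom=_ACCEPTOR_ATOM[ka.res_name],
                distance=2.9, donor_side="B"))
        hb_frac.append(frac)

    sites = []
    if needs_free_nterm:
        # cap the chain so the free C-terminus falls on an inert residue
        sites = [PlantedSite(residue=("GLY", 99999), distance=25.0,
                             probe=("ALA", 88888))]
    spec = PlantSpec(
        hbs=hbs, sbs=sbs, sites=sites, seed=seed, chains=chains,
        group_names=group_names,
        free_termini=(chain_a,) if needs_free_nterm else ())
    # ledger order: HBs first, then SBs
    fractions = {i: f for i, f in enumerate(hb_frac + sb_frac)}
    return spec, fractions


class LifetimeEntry(NamedTuple):
    complex_id: int
    residue_a: str
    backbone_a: str
    residue_b: str
    backbone_b: str
    kind: str
    lifetime_percent: float


def _read_rows(name: str) -> list[list[str]]:
    text = (resources.files("ifacekit") / "data" / name).read_text()
    rows = []
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def load_docked_contact_counts() -> dict[int, tuple[int, int]]:
    """Per-side interacting-atom counts of the ten docked candidate poses."""
    return {
        int(r[0]): (int(r[1]), int(r[2]))
        for r in _read_rows("docked_contact_counts.tsv")
    }


def load_md_lifetimes() -> dict[int, list[LifetimeEntry]]:
    """Specific-interaction lifetimes of the MD-simulated leading complexes."""
    out: dict[int, list[LifetimeEntry]] = {}
    for r in _read_rows("md_interaction_lifetimes.tsv"):
        entry = LifetimeEntry(
            int(r[0]), r[1], r[2], r[3], r[4], r[5], float(r[6]))
        out.setdefault(entry.complex_id, []).append(entry)
    return out


def lifetimes_as_records(
    complex_id: int,
    total_frames: int = 100,
    chain_a: str = "A",
    chain_b: str = "B",
) -> list[OccupancyRecord]:
    """Published lifetimes as occupancy records over ``total_frames`` frames.

    Lifetime percentages are integers over a 100-frame normalization, so the
    conversion is exact at the default.
    """
    records = []
    for e in load_md_lifetimes()[complex_id]:
        inter = SpecificInteraction(
            kind=e.kind,
            residue_a=parse_residue_label(e.residue_a, chain_a),
            residue_b=parse_residue_label(e.residue_b, chain_b),
            atoms_a=(), atoms_b=(),
            backbone_a=e.backbone_a, backbone_b=e.backbone_b,
        )
        frames_present = int(round(e.lifetime_percent / 100.0 * total_frames))
        records.append(OccupancyRecord(inter, frames_present, total_frames))
    return records
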