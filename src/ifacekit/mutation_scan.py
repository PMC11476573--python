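"""Rule-based triage of interface point mutations.

Classification argues qualitatively from the wild-type geometry; no
side-chain rebuilding or energetics. The ordered rule set:

1. residue participates in a salt bridge and the variant reverses the
   side-chain charge sign            -> weaken / charge_reversal_at_SB
2. residue donates or accepts a hydrogen bond and the variant retains an
   equivalent donor/acceptor          -> neutral / hb_preserving_swap
3. residue in steric contact and the variant loses >= 3 side-chain heavy
   atoms, or loses a formal charge engaged electrostatically
                                      -> weaken / bulk_and_charge_loss
4. residue within the proximal band with no specific interaction, and the
   variant's new charge is opposite to a charged partner residue nearby
                                      -> strengthen_candidate / new_SB_possible
5. distal                             -> none / no_interface_role

The rule order is configurable rather than hard-coded because no single
ordering is canonical for this kind of qualitative reasoning.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .contact_analysis import ContactSet
from .specific_interactions import SpecificInteraction
from .structure_model import AMINO3, ResidueKey, Structure

__all__ = [
    "MutationSpec",
    "MutationEffect",
    "MutationRuleConfig",
    "classify_mutation_effect",
    "scan_catalog",
    "read_catalog",
]

#: side-chain formal charge at pH 7 (same convention as charge accounting)
SIDECHAIN_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

#: heavy side-chain atom counts of the standard amino acids
SIDECHAIN_HEAVY = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}

#: substitutions that retain an equivalent H-bond donor/acceptor
DEFAULT_HB_EQUIVALENT = {
    ("ASP", "ASN"), ("ASN", "ASP"),
    ("GLU", "GLN"), ("GLN", "GLU"),
    ("SER", "THR"), ("THR", "SER"),
}

DEFAULT_RULE_ORDER = (
    "charge_reversal_at_SB",
    "hb_preserving_swap",
    "bulk_and_charge_loss",
    "new_SB_possible",
)


@dataclass(frozen=True)
class MutationSpec:
    """One point mutation, e.g. Glu505Lys on the albumin chain."""

    residue: ResidueKey
    wild_type: str
    variant: str
    source_label: str = ""

    @classmethod
    def from_label(cls, label: str, chain_id: str) -> "MutationSpec":
        """Parse a ``Glu505Lys``-style label."""
        wild, rest = label[:3].upper(), label[3:]
        variant = rest[-3:].upper()
        seq = int(rest[:-3])
        if wild not in AMINO3 or variant not in AMINO3:
            raise ValueError(f"cannot parse mutation label {label!r}")
        return cls(ResidueKey(chain_id, seq, "", wild), wild, variant, label)


@dataclass
class MutationEffect:
    mutation: MutationSpec
    interface_status: str  # specific_interaction | steric_contact | proximal | distal
    affected_interactions: list[SpecificInteraction]
    predicted_effect: str  # weaken | neutral | strengthen_candidate | none
    rationale_code: str | None
    detail: str = ""


@dataclass
class MutationRuleConfig:
    hb_equivalent: set[tuple[str, str]] = field(
        default_factory=lambda: set(DEFAULT_HB_EQUIVALENT))
    rule_order: tuple[str, ...] = DEFAULT_RULE_ORDER
    min_heavy_atom_loss: int = 3


def _short(key: ResidueKey) -> tuple:
    return (key.chain_id, key.res_seq, key.insertion_code)


def _min_distance_to_partner(
    s: Structure, key: ResidueKey, partner_group: str,
) -> tuple[float, ResidueKey | None]:
    partner_idx = s.group_atom_indices(partner_group, include_hydrogens=False)
    own_idx = [i for i in s.residues[key] if not s.atoms[i].is_hydrogen]
    dmat = np.linalg.norm(
        s.coords[own_idx][:, None, :] - s.coords[partner_idx][None, :, :],
        axis=-1)
    flat = int(np.argmin(dmat))
    nearest = s.residue_of_atom(int(partner_idx[flat % dmat.shape[1]]))
    return float(dmat.min()), nearest


def classify_mutation_effect(
    m: MutationSpec,
    cs: ContactSet,
    interactions: Sequence[SpecificInteraction],
    s: Structure,
    proximal_cutoff: float = 8.0,
    config: MutationRuleConfig | None = None,
) -> MutationEffect:
    """Classify one mutation's predicted consequence for the complex."""
    config = config or MutationRuleConfig()
    key = s.find_residue(
        m.residue.chain_id, m.residue.res_seq, m.residue.insertion_code)
    if key.res_name != m.wild_type.upper():
        raise ValueError(
            f"wild-type mismatch for {m.source_label or m.wild_type}: "
            f"structure has {key.res_name} at {key.chain_id}/{key.res_seq}")

    own_group = s.group_of_chain(key.chain_id)
    partner_group = next(g for g in s.groups if g != own_group)

    affected = [i for i in interactions if i.involves(key)]
    in_contact = any(
        _short(r) == _short(key)
        for r in (cs.interface_residues_a + cs.interface_residues_b))
    dmin, nearest = _min_distance_to_partner(s, key, partner_group)

    if affected:
        status = "specific_interaction"
    elif in_contact:
        status = "steric_contact"
    elif dmin <= proximal_cutoff:
        status = "proximal"
    else:
        status = "distal"

    wild_q = SIDECHAIN_CHARGE.get(m.wild_type.upper(), 0)
    var_q = SIDECHAIN_CHARGE.get(m.variant.upper(), 0)
    in_sb = any(i.kind == "SB" for i in affected)
    in_hb = any(i.kind == "HB" for i in affected)
    heavy_loss = (SIDECHAIN_HEAVY[m.wild_type.upper()]
                  - SIDECHAIN_HEAVY[m.variant.upper()])

    def rule_charge_reversal() -> MutationEffect | None:
        if in_sb and wild_q * var_q < 0:
            return MutationEffect(
                m, status, affected, "weaken", "charge_reversal_at_SB",
                f"{m.source_label or key.label}: charge sign flips at a salt "
                "bridge")
        return None

    def rule_hb_preserving() -> MutationEffect | None:
        if in_hb and (m.wild_type.upper(), m.variant.upper()) in config.hb_equivalent:
            return MutationEffect(
                m, status, affected, "neutral", "hb_preserving_swap",
                "equivalent donor/acceptor retained")
        return None

    def rule_bulk_loss() -> MutationEffect | None:
        if status in ("specific_interaction", "steric_contact"):
            charge_engaged = in_sb and abs(var_q) < abs(wild_q)
            if heavy_loss >= config.min_heavy_atom_loss or charge_engaged:
                return MutationEffect(
                    m, status, affected, "weaken", "bulk_and_charge_loss",
                    f"loses {max(heavy_loss, 0)} side-chain heavy atoms"
                    + ("; engaged charge lost" if charge_engaged else ""))
        return None

    def rule_new_sb() -> MutationEffect | None:
        if affected or dmin > proximal_cutoff or var_q == 0 or var_q == wild_q:
            return None
        # a charged partner residue of opposite sign within the proximal band
        own_idx = [i for i in s.residues[key] if not s.atoms[i].is_hydrogen]
        for pkey in s.polymer_residues():
            if s.group_of_chain(pkey.chain_id) != partner_group:
                continue
            pq = SIDECHAIN_CHARGE.get(pkey.res_name, 0)
            if pq * var_q >= 0:
                continue
            p_idx = [i for i in s.residues[pkey] if not s.atoms[i].is_hydrogen]
            d = np.linalg.norm(
                s.coords[own_idx][:, None, :] - s.coords[p_idx][None, :, :],
                axis=-1).min()
            if d <= proximal_cutoff:
                return MutationEffect(
                    m, status, affected, "strengthen_candidate",
                    "new_SB_possible",
                    f"opposite charge {pkey.label} within "
                    f"{proximal_cutoff:g} A")
        return None

    rules = {
        "charge_reversal_at_SB": rule_charge_reversal,
        "hb_preserving_swap": rule_hb_preserving,
        "bulk_and_charge_loss": rule_bulk_loss,
        "new_SB_possible": rule_new_sb,
    }
    if status == "distal":
        return MutationEffect(
            m, status, [], "none", "no_interface_role",
            f"min distance to partner {dmin:.1f} A")
    for name in config.rule_order:
        result = rules[name]()
        if result is not None:
            return result
    return MutationEffect(
        m, status, affected, "neutral", None,
        "interface residue; substitution matches no triage rule")


@dataclass
class CatalogScan:
    effects: list[MutationEffect]
    summary: Counter
    errors: dict[str, str]


def scan_catalog(
    catalog: Sequence[MutationSpec],
    cs: ContactSet,
    interactions: Sequence[SpecificInteraction],
    s: Structure,
    proximal_cutoff: float = 8.0,
    config: MutationRuleConfig | None = None,
) -> CatalogScan:
    """Classify every catalog entry; per-entry errors do not stop the scan."""
    if not catalog:
        raise ValueError("empty mutation catalog")
    seen: set[tuple] = set()
    effects: list[MutationEffect] = []
    errors: dict[str, str] = {}
    for m in catalog:
        ident = (_short(m.residue), m.wild_type.upper(), m.variant.upper())
        if ident in seen:
            warnings.warn(
                f"duplicate catalog entry {m.source_label or ident}; skipped")
            continue
        seen.add(ident)
        try:
            effects.append(classify_mutation_effect(
                m, cs, interactions, s, proximal_cutoff, config))
        except (KeyError, ValueError) as exc:
            errors[m.source_label or str(ident)] = str(exc)
    summary = Counter(e.predicted_effect for e in effects)
    return CatalogScan(effects, summary, errors)


def read_catalog(path: str | Path) -> list[MutationSpec]:
    """Read a tab-separated catalog: chain, res_seq, wild_type, variant, label."""
    specs = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            chain, seq, wild, variant = row[0], int(row[1]), row[2], row[3]
            label = row[4] if len(row) > 4 else f"{wild.capitalize()}{seq}{variant.capitalize()}"
            specs.append(MutationSpec(
                ResidueKey(chain, seq, "", wild.upper()),
                wild.upper(), variant.upper(), label))
    return specs
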