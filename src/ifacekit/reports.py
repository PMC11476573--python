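"""Plain tab-separated report writers in the interface-table style.

Reports are diffable text: one row per complex or per interaction, with
specific interactions rendered in the literature notation
(``Asp38-Lys622 (SB)``, ``Cys34^O-Gln807 (HB)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .contact_analysis import ContactSet, RankingReport, SiteProximityReport
from .specific_interactions import SpecificInteraction
from .structure_model import ResidueKey
from .trajectory_analysis import OccupancyRecord

__all__ = [
    "contact_table",
    "interaction_lines",
    "lifetime_table",
    "ranking_table",
    "site_table",
    "SharedInterfaceReport",
    "shared_interface_report",
]


def _residue_list(keys: Sequence[ResidueKey]) -> str:
    return ", ".join(k.label for k in keys)


def contact_table(
    complex_id: object,
    cs: ContactSet,
    interactions: Sequence[SpecificInteraction] = (),
) -> str:
    """One Table-style row: counts, interface residues, interactions."""
    header = ("complex_id\tn_atoms_{a}\tn_atoms_{b}\tcutoff_A\t"
              "hydrogens_included\tresidues_{a}\tresidues_{b}\t"
              "specific_interactions\n").format(a=cs.group_a, b=cs.group_b)
    row = "\t".join([
        str(complex_id),
        str(cs.n_atoms_a), str(cs.n_atoms_b),
        f"{cs.cutoff:g}", str(cs.include_hydrogens).lower(),
        _residue_list(cs.interface_residues_a),
        _residue_list(cs.interface_residues_b),
        "; ".join(i.notation() for i in interactions),
    ])
    return header + row + "\n"


def interaction_lines(interactions: Sequence[SpecificInteraction]) -> str:
    return "\n".join(i.notation() for i in interactions) + "\n"


def lifetime_table(records: Sequence[OccupancyRecord]) -> str:
    lines = ["interaction\tkind\tframes_present\ttotal_frames\tlifetime_percent"]
    for r in records:
        lines.append("\t".join([
            r.interaction.notation(), r.interaction.kind,
            str(r.frames_present), str(r.total_frames),
            f"{r.lifetime_percent:.1f}",
        ]))
    return "\n".join(lines) + "\n"


def ranking_table(report: RankingReport) -> str:
    lines = [f"# engagement score: {report.score}",
             "rank\tcomplex_id\tn_atoms_a\tn_atoms_b\tscore"]
    for rank, (cid, na, nb, score) in enumerate(report.entries, start=1):
        lines.append(f"{rank}\t{cid}\t{na}\t{nb}\t{score:g}")
    return "\n".join(lines) + "\n"


def site_table(reports: Sequence[SiteProximityReport]) -> str:
    lines = ["site\tmin_distance_A\tcategory\tnearest_partner_residue"]
    for r in reports:
        lines.append("\t".join([
            r.site_residue.label, f"{r.min_distance_to_partner:.2f}",
            r.category, r.nearest_partner_residue.label,
        ]))
    return "\n".join(lines) + "\n"


# --- comparative topology ---------------------------------------------------


@dataclass
class SharedInterfaceReport:
    """Interface-residue overlap of one common group across two complexes."""

    common_group: str
    residues_a: set[ResidueKey]
    residues_b: set[ResidueKey]
    shared: set[ResidueKey]
    only_a: set[ResidueKey]
    only_b: set[ResidueKey]
    #: domain -> (n in complex a, n in complex b, n shared)
    domain_tally: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = [f"# common group: {self.common_group}",
                 "domain\tn_complex_a\tn_complex_b\tn_shared"]
        for dom, (na, nb, ns) in self.domain_tally.items():
            lines.append(f"{dom}\t{na}\t{nb}\t{ns}")
        lines.append("")
        lines.append(f"shared_residues\t{_residue_list(sorted(self.shared, key=ResidueKey.sort_key))}")
        lines.append(f"only_complex_a\t{_residue_list(sorted(self.only_a, key=ResidueKey.sort_key))}")
        lines.append(f"only_complex_b\t{_residue_list(sorted(self.only_b, key=ResidueKey.sort_key))}")
        return "\n".join(lines) + "\n"


def _short(key: ResidueKey) -> tuple:
    return (key.res_seq, key.insertion_code)


def shared_interface_report(
    cs_a: ContactSet,
    cs_b: ContactSet,
    common_group: str,
    domains: dict[str, tuple[int, int]] | None = None,
) -> SharedInterfaceReport:
    """Intersect the common group's interface residues across two complexes.

    With a domain partition (e.g. albumin's DI/DII/DIII), tallies per-domain
    participation, answering which domains a common partner surface engages
    in each complex.
    """
    def side_residues(cs: ContactSet) -> set[ResidueKey]:
        if cs.group_a == common_group:
            return set(cs.interface_residues_a)
        if cs.group_b == common_group:
            return set(cs.interface_residues_b)
        raise ValueError(
            f"group {common_group!r} absent from contact set "
            f"({cs.group_a}, {cs.group_b})")

    ra, rb = side_residues(cs_a), side_residues(cs_b)
    short_b = {_short(k) for k in rb}
    short_a = {_short(k) for k in ra}
    shared = {k for k in ra if _short(k) in short_b}
    only_a = {k for k in ra if _short(k) not in short_b}
    only_b = {k for k in rb if _short(k) not in short_a}

    tally: dict[str, tuple[int, int, int]] = {}
    for dom, (lo, hi) in (domains or {}).items():
        in_dom = lambda ks: sum(1 for k in ks if lo <= k.res_seq <= hi)
        tally[dom] = (in_dom(ra), in_dom(rb), in_dom(shared))
    return SharedInterfaceReport(
        common_group, ra, rb, shared, only_a, only_b, tally)
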