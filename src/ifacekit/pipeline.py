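"""End-to-end orchestration: contacts -> interactions -> dynamics -> reports."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .contact_analysis import (
    close_contacts,
    functional_site_proximity,
    glycosite_contacts,
    rank_complexes,
)
from .mutation_scan import read_catalog, scan_catalog
from .reports import (
    contact_table,
    lifetime_table,
    ranking_table,
    site_table,
)
from .specific_interactions import detect_specific_interactions
from .structure_model import (
    assign_protonation,
    load_structure,
    parse_residue_label,
)
from .trajectory_analysis import (
    ca_rmsd_series,
    endpoint_contact_table,
    load_multimodel_pdb,
    persistence_filter,
    track_interactions,
)

logger = logging.getLogger("ifacekit")

__all__ = ["run_pipeline", "ComplexAnalysis", "PipelineResult"]


@dataclass
class ComplexAnalysis:
    complex_id: object
    contact_set: object
    interactions: list
    occupancy: list | None = None
    persistent: list | None = None
    endpoint: object | None = None
    rmsd: object | None = None


@dataclass
class PipelineResult:
    analyses: dict[str, ComplexAnalysis]
    ranking: object
    outputs: dict[str, str] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def _parse_ref(ref: str) -> tuple[str, str]:
    chain, label = ref.split(":", 1)
    return chain, label


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every analysis stage for each configured input complex.

    Per complex: close contacts and specific interactions; if the input is a
    multi-model file, occupancy tracking, the persistence filter, the
    endpoint contact table and the Ca-RMSD series; then ranking across
    complexes, glycosylation / functional-site reports and, when a catalog
    is configured, the mutation scan. A stage failure is recorded under the
    stage name and the run continues with partial outputs retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    analyses: dict[str, ComplexAnalysis] = {}
    failures: dict[str, str] = {}
    outputs: dict[str, str] = {}
    two_groups = tuple(sorted(config.group_spec))[:2]

    for cid, path in config.inputs.items():
        try:
            is_traj = _is_multimodel(path)
            if is_traj:
                traj = load_multimodel_pdb(
                    path, config.group_spec,
                    free_termini=config.free_termini,
                    hetero_charges=config.hetero_charges)
                s = traj.topology
            else:
                traj = None
                s = load_structure(
                    path, config.group_spec,
                    free_termini=config.free_termini,
                    hetero_charges=config.hetero_charges)
            overrides = {
                _key_for(s, ref): state
                for ref, state in config.protonation_overrides.items()
            }
            assign_protonation(s, overrides, default_his=config.default_his)
            s.assign_glycan_parents()

            cs = close_contacts(
                s, config.contact_cutoff,
                include_hydrogens=config.include_hydrogens)
            inters = detect_specific_interactions(
                s, config.hb_criteria, config.sb_max_distance)
            analysis = ComplexAnalysis(cid, cs, inters)

            if traj is not None and traj.n_frames > 1:
                records = track_interactions(
                    traj, config.hb_criteria, config.sb_max_distance)
                analysis.occupancy = records
                analysis.persistent = persistence_filter(
                    records, config.persistence_threshold)
                analysis.endpoint = endpoint_contact_table(
                    traj, config.contact_cutoff,
                    include_hydrogens=config.include_hydrogens)
                analysis.rmsd = ca_rmsd_series(traj)
                _write(outdir / f"{cid}.lifetimes.tsv",
                       lifetime_table(records), outputs)
                _write(outdir / f"{cid}.rmsd.tsv",
                       _rmsd_tsv(analysis.rmsd), outputs)
            _write(outdir / f"{cid}.contacts.tsv",
                   contact_table(cid, cs, inters), outputs)
            analyses[cid] = analysis
        except Exception as exc:  # keep going; report per-stage failure
            logger.error("complex %s failed: %s", cid, exc)
            failures[f"complex:{cid}"] = str(exc)

    ranking = None
    if analyses:
        try:
            ranking = rank_complexes(
                {cid: a.contact_set for cid, a in analyses.items()},
                score=config.engagement_score)
            _write(outdir / "ranking.tsv", ranking_table(ranking), outputs)
        except Exception as exc:
            failures["ranking"] = str(exc)

    for cid, a in analyses.items():
        s = a.contact_set.structure
        try:
            if config.glyco_residues:
                glyco = [
                    parse_residue_label(lbl, chain)
                    for chain, lbl in map(_parse_ref, config.glyco_residues)]
                gc = glycosite_contacts(a.contact_set, glyco, a.interactions)
                lines = [f"{s.residue_of_atom(i).label}\t"
                         f"{s.residue_of_atom(j).label}\t{d:.2f}"
                         for i, j, d in gc.pairs]
                _write(outdir / f"{cid}.glyco.tsv",
                       "\n".join(["res_a\tres_b\tdistance_A"] + lines) + "\n",
                       outputs)
            if config.functional_sites:
                sites = [
                    parse_residue_label(lbl, chain)
                    for chain, lbl in map(_parse_ref, config.functional_sites)]
                sp = functional_site_proximity(
                    s, sites, config.proximal_cutoff, config.contact_cutoff)
                _write(outdir / f"{cid}.sites.tsv", site_table(sp), outputs)
            if config.mutation_catalog:
                catalog = read_catalog(config.mutation_catalog)
                scan = scan_catalog(
                    catalog, a.contact_set, a.interactions, s,
                    config.proximal_cutoff)
                _write(outdir / f"{cid}.mutations.tsv",
                       _mutation_tsv(scan), outputs)
        except Exception as exc:
            failures[f"reports:{cid}"] = str(exc)

    manifest = {
        "ifacekit_version": __version__,
        "python": sys.version.split()[0],
        "config": config.echo(),
        "outputs": sorted(outputs),
        "failures": failures,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return PipelineResult(analyses, ranking, outputs, failures)


def _key_for(s, ref: str):
    chain, label = _parse_ref(ref)
    key = parse_residue_label(label, chain)
    return s.find_residue(chain, key.res_seq, key.insertion_code)


def _is_multimodel(path: str) -> bool:
    try:
        with open(path) as fh:
            return sum(1 for line in fh if line.startswith("MODEL ")) > 1
    except (OSError, UnicodeDecodeError):
        return False


def _write(path: Path, text: str, outputs: dict[str, str]) -> None:
    path.write_text(text)
    outputs[path.name] = str(path)


def _rmsd_tsv(series) -> str:
    lines = ["frame\trmsd_A"]
    for f, v in enumerate(series.values):
        lines.append(f"{f}\t{v:.4f}")
    return "\n".join(lines) + "\n"


def _mutation_tsv(scan) -> str:
    lines = ["label\tstatus\taffected\teffect\trationale"]
    for e in scan.effects:
        lines.append("\t".join([
            e.mutation.source_label,
            e.interface_status,
            "; ".join(i.notation() for i in e.affected_interactions),
            e.predicted_effect,
            e.rationale_code or "",
        ]))
    for label, msg in scan.errors.items():
        lines.append(f"{label}\tERROR\t\t\t{msg}")
    return "\n".join(lines) + "\n"
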