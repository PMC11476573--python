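"""Per-frame interaction tracking, occupancy/lifetime, persistence, RMSD.

An interaction's identity across frames is its (residue pair, kind) key, not
the atom-level geometry: any qualifying atom geometry in a frame counts the
frame as present. Occupancy is the fraction of frames present; the lifetime
percentage is occupancy x 100, matching how interface interaction tables
report persistence over a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .contact_analysis import ContactSet, close_contacts
from .specific_interactions import (
    HBCriteria,
    SpecificInteraction,
    detect_specific_interactions,
)
from .structure_model import Structure

__all__ = [
    "Trajectory",
    "OccupancyRecord",
    "RmsdSeries",
    "track_interactions",
    "persistence_filter",
    "endpoint_contact_table",
    "ca_rmsd_series",
    "load_multimodel_pdb",
]


@dataclass
class Trajectory:
    """Fixed-topology multi-frame coordinate set (Angstrom)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ns; uniform spacing assumed if None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{len(self.topology.atoms)}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @classmethod
    def from_mdanalysis(cls, universe, topology: Structure) -> "Trajectory":
        """Thin adapter for any trajectory format MDAnalysis can read."""
        frames = np.array(
            [universe.atoms.positions.copy() for _ in universe.trajectory],
            dtype=float)
        return cls(topology, frames)


def load_multimodel_pdb(
    path: str | Path,
    group_spec: Mapping[str, Iterable[str]],
    **load_kwargs,
) -> Trajectory:
    """Read a multi-model PDB: model 1 is the topology, models are frames."""
    from .structure_model import load_structure

    topology = load_structure(path, group_spec, **load_kwargs)
    st = gemmi.read_structure(str(path))
    frames = []
    for model in st:
        xyz = []
        for chain in model:
            for res in chain:
                for atom in res:
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        frames.append(xyz)
    frames_arr = np.asarray(frames, dtype=float)
    return Trajectory(topology, frames_arr)


@dataclass
class OccupancyRecord:
    """A specific interaction plus the fraction of frames it is present in."""

    interaction: SpecificInteraction
    frames_present: int
    total_frames: int

    @property
    def occupancy(self) -> float:
        return self.frames_present / self.total_frames

    @property
    def lifetime_percent(self) -> float:
        return 100.0 * self.occupancy

    @property
    def key(self) -> tuple:
        return self.interaction.pair_key()


@dataclass
class RmsdSeries:
    """Root-mean-square deviation per frame over an atom selection."""

    reference_frame: int
    values: np.ndarray  # Angstrom, one per frame
    selection: str = "CA"
    superposed: bool = True


# --- occupancy tracking -----------------------------------------------------


def track_interactions(
    t: Trajectory,
    hb_criteria: HBCriteria | None = None,
    sb_max_distance: float = 4.0,
    groups: tuple[str, str] | None = None,
) -> list[OccupancyRecord]:
    """Run HB + SB detection in every frame and tally per-key occupancy.

    A record exists for every interaction observed in at least one frame.
    Results are ordered by descending lifetime, then by residue-pair key, so
    repeated runs are byte-identical.
    """
    if t.n_frames == 0:
        raise ValueError("empty trajectory")
    s = t.topology
    original = s.coords.copy()
    counts: dict[tuple, int] = {}
    exemplar: dict[tuple, SpecificInteraction] = {}
    try:
        for f in range(t.n_frames):
            s.set_coords(t.frames[f])
            found = detect_specific_interactions(
                s, hb_criteria, sb_max_distance, groups=groups)
            seen = set()
            for inter in found:
                key = inter.pair_key()
                if key in seen:
                    continue
                seen.add(key)
                counts[key] = counts.get(key, 0) + 1
                if key not in exemplar or (
                        inter.distance < exemplar[key].distance):
                    exemplar[key] = inter
    finally:
        s.set_coords(original)
    records = [
        OccupancyRecord(exemplar[k], counts[k], t.n_frames) for k in counts]
    records.sort(key=lambda r: (-r.frames_present, r.key))
    return records


def persistence_filter(
    records: Sequence[OccupancyRecord],
    threshold_percent: float = 50.0,
) -> list[OccupancyRecord]:
    """Keep interactions whose lifetime is strictly greater than the threshold.

    Strict comparison matches the "persist over 50%" reading; survivors are
    ordered by descending lifetime.
    """
    if not (0.0 <= threshold_percent <= 100.0):
        raise ValueError("threshold must be within [0, 100]")
    kept = [r for r in records if r.lifetime_percent > threshold_percent]
    kept.sort(key=lambda r: (-r.lifetime_percent, r.key))
    return kept


def endpoint_contact_table(
    t: Trajectory,
    cutoff: float = 3.5,
    include_hydrogens: bool = False,
    groups: tuple[str, str] | None = None,
) -> ContactSet:
    """Close contacts evaluated on the final frame only."""
    s = t.topology
    original = s.coords.copy()
    try:
        s.set_coords(t.frames[-1])
        return close_contacts(
            s, cutoff, include_hydrogens=include_hydrogens, groups=groups)
    finally:
        s.set_coords(original)


# --- RMSD -------------------------------------------------------------------


def _selection_indices(s: Structure, selection: str) -> np.ndarray:
    if selection == "CA":
        idx = [a.index for a in s.atoms if a.name == "CA"]
    elif selection == "heavy":
        idx = [a.index for a in s.atoms if not a.is_hydrogen]
    elif selection == "all":
        idx = [a.index for a in s.atoms]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    return np.asarray(idx, dtype=int)


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal rigid-body (Kabsch) superposition RMSD of two point sets."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    aligned = rot.apply(mob_c)
    return float(np.sqrt(((aligned - ref_c) ** 2).sum(axis=1).mean()))


def plain_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    return float(np.sqrt(((mobile - reference) ** 2).sum(axis=1).mean()))


def ca_rmsd_series(
    t: Trajectory,
    reference: int = 0,
    superpose: bool = True,
    selection: str = "CA",
) -> RmsdSeries:
    """Per-frame RMSD onto a reference frame over the selection (default Ca).

    The fit, when requested, is performed jointly on the selection across
    both groups, so the series tracks whole-complex stabilization.
    """
    if not (0 <= reference < t.n_frames):
        raise IndexError(f"reference frame {reference} out of range")
    sel = _selection_indices(t.topology, selection)
    if len(sel) == 0:
        raise ValueError(f"no atoms in selection {selection!r}")
    ref = t.frames[reference][sel]
    values = np.empty(t.n_frames, dtype=float)
    for f in range(t.n_frames):
        mob = t.frames[f][sel]
        values[f] = superposed_rmsd(mob, ref) if superpose else plain_rmsd(mob, ref)
    return RmsdSeries(reference, values, selection, superpose)
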