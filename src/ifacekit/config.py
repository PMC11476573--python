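"""Pipeline configuration: cutoffs, group spec, site lists, thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .specific_interactions import HBCriteria

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Validated knobs for a full interface-characterization run."""

    inputs: dict[str, str] = field(default_factory=dict)  # complex id -> path
    group_spec: dict[str, list[str]] = field(
        default_factory=lambda: {"A": ["A"], "B": ["B"]})
    contact_cutoff: float = 3.5
    include_hydrogens: bool = False
    sb_max_distance: float = 4.0
    hb_criteria: HBCriteria = field(default_factory=HBCriteria)
    proximal_cutoff: float = 8.0
    persistence_threshold: float = 50.0
    engagement_score: str = "min_side"
    glyco_residues: list[str] = field(default_factory=list)  # "B:Asn685"
    functional_sites: list[str] = field(default_factory=list)  # "A:Cys34"
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    mutation_catalog: str | None = None
    protonation_overrides: dict[str, str] = field(default_factory=dict)
    default_his: str = "HIE"
    free_termini: list[str] = field(default_factory=list)
    hetero_charges: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "iface_out"

    def __post_init__(self) -> None:
        for name, value in [
            ("contact_cutoff", self.contact_cutoff),
            ("sb_max_distance", self.sb_max_distance),
            ("proximal_cutoff", self.proximal_cutoff),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not (0.0 <= self.persistence_threshold <= 100.0):
            raise ValueError(
                "persistence_threshold must be within [0, 100], got "
                f"{self.persistence_threshold}")

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        hb = data.pop("hb_criteria", None)
        cfg = cls(**data)
        if hb:
            cfg.hb_criteria = HBCriteria(**hb)
        return cfg

    def echo(self) -> dict[str, Any]:
        """Config as plain data for the run manifest."""
        out = dict(self.__dict__)
        out["hb_criteria"] = dict(self.hb_criteria.__dict__)
        return out


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_mapping(data)
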