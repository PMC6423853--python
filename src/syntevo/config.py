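"""Pipeline configuration: a small YAML-backed schema with strict defaults.

The config round-trips read -> write -> read identically. Time constants
default to the subgroup calibration used throughout (1.72 Myr to the
subgroup common ancestor, 0.92 Myr to the island-sister split).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .pipeline import PairParams


@dataclass
class SimulateConfig:
    scale: float = 0.02  # fraction of the full ~125 Mb karyotype
    markers_per_mb: float = 400.0  # anchor density of the scaled genome
    scenario: str = "template"  # "template" or "none"
    with_repeats: bool = True


@dataclass
class TreeConfig:
    t_subgroup: float = 1.72  # Myr to the subgroup common ancestor
    t_island_split: float = 0.92  # Myr to the island-sister split
    mainland: str = "subobscura"
    island_sister: str = "madeirensis"
    island_lineage: str = "guanche"


@dataclass
class StatsConfig:
    window: int = 500_000
    step: int = 250_000
    envelope_replicates: int = 1000


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "syntevo_out"
    reference: str = "subobscura"
    other: str = "guanche"
    outgroup: str = "outgroup"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    params: PairParams = field(default_factory=PairParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    taxa: dict = field(default_factory=dict)  # taxon -> {fasta, gff3, bed} for external input

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for key, sub in (
            ("simulate", SimulateConfig),
            ("tree", TreeConfig),
            ("params", PairParams),
            ("stats", StatsConfig),
        ):
            if key in data:
                kwargs[key] = sub(**data.pop(key))
        known = {"seed", "outdir", "reference", "other", "outgroup", "taxa"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
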