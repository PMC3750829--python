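"""Pipeline configuration: one structured YAML document, validated at load.

Sections mirror the stage parameter objects (sim -> SimConfig, classify ->
ClassifierParams, map -> MapParams) plus genotyping options and report
settings.  Unknown keys are rejected so typos fail fast, and the fully
populated config is echoed into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .linkmap import MapParams
from .readclass import ClassifierParams
from .simdata import SimConfig

__all__ = ["PipelineConfig", "GenotypeOptions", "ReportOptions", "load_config"]


@dataclass(frozen=True)
class GenotypeOptions:
    informative_only: bool = False
    split_at_turning_points: bool = False
    min_segment_reads: int = 5
    min_score: int = 3


@dataclass(frozen=True)
class ReportOptions:
    genome_size_bp: float | None = None  # defaults to the simulated genome size
    experimental_table: str | None = None  # optional concordance CSV


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    classify: ClassifierParams = field(default_factory=ClassifierParams)
    genotype: GenotypeOptions = field(default_factory=GenotypeOptions)
    map: MapParams = field(default_factory=MapParams)
    report: ReportOptions = field(default_factory=ReportOptions)
    seed: int | None = None  # overrides sim.seed when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    def to_dict(self) -> dict[str, Any]:
        def plain(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

        return {
            "sim": plain(self.sim),
            "classify": plain(self.classify),
            "genotype": plain(self.genotype),
            "map": plain(self.map),
            "report": plain(self.report),
            "seed": self.seed,
            "log_level": self.log_level,
        }


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in config section '{name}': {sorted(unknown)}")
    kwargs = dict(section)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML; CLI flag overrides take precedence."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        section, _, leaf = key.partition(".")
        if leaf:
            raw.setdefault(section, {})[leaf] = val
        else:
            raw[section] = val
    known = {"sim", "classify", "genotype", "map", "report", "seed", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    return PipelineConfig(
        sim=_build(SimConfig, raw.get("sim", {}), "sim"),
        classify=_build(ClassifierParams, raw.get("classify", {}), "classify"),
        genotype=_build(GenotypeOptions, raw.get("genotype", {}), "genotype"),
        map=_build(MapParams, raw.get("map", {}), "map"),
        report=_build(ReportOptions, raw.get("report", {}), "report"),
        seed=raw.get("seed"),
        log_level=str(raw.get("log_level", "INFO")),
    )
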