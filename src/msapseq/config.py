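"""Validated pipeline configuration.

One structured YAML file configures every stage; unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .contigs import DEFAULT_MID_TABLE
from .simulate import SimulationConfig

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    """All module parameters plus the simulation study conditions."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0

    # synthetic-data study conditions
    genome_length: int = 20_000
    target_gaattc_sites: int = 36
    target_ccgg_sites: int = 36
    n_changes_per_pair: int = 6
    n_shared: int = 3
    read_error_rate: float = 0.005
    coverage: int = 10
    replicates_per_variant: int = 4

    # landscape / matrix
    bin_width: int = 1

    # capacity planning
    mean_amplicon_length: float = 200
    amplicons_per_combination: float = 300
    n_pooled_samples: int = 4
    target_coverage: float = 10
    device_capacity: float = 35_000_000
    max_combos: int = 6

    # read processing
    mid_table: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_MID_TABLE))
    demux_max_mismatch: int = 0
    adaptors: list[str] = Field(default_factory=list)
    trim_min_length: int = 40
    trim_min_quality: float = 20.0

    # clustering / differential extraction
    min_identity: float = 0.97
    min_reads: int = 2
    e_threshold: float = 1e-5

    @field_validator("mid_table")
    @classmethod
    def _unique_mids(cls, v: dict[str, str]) -> dict[str, str]:
        if len(set(v.values())) != len(v):
            raise ValueError("duplicate MID barcodes")
        return v

    def simulation(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed,
            genome_length=self.genome_length,
            target_gaattc_sites=self.target_gaattc_sites,
            target_ccgg_sites=self.target_ccgg_sites,
            n_changes_per_pair=self.n_changes_per_pair,
            n_shared=self.n_shared,
            read_error_rate=self.read_error_rate,
            coverage=self.coverage,
            replicates_per_variant=self.replicates_per_variant,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
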