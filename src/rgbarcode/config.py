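"""Run configuration: one validated document fully determines a run.

Every stochastic stage takes an explicit seed, so a config plus the
package version pins the outputs bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

SCHEMA_VERSION = 1


class DesignConfig(BaseModel):
    colors: list[str] = Field(default=["red", "green", "blue"], min_length=1)
    min_distance: int = 8
    library_size: int = Field(default=0, ge=0)  # 0 = no FASTA library output
    seed: int = 0


class SimulateConfig(BaseModel):
    n_cells: int = Field(default=1000, ge=1)
    moi_per_vector: dict[str, float] = Field(default={"red": 1.4, "green": 1.4, "blue": 1.4})
    depth: int = Field(default=20_000, ge=0)
    error_rate: float = Field(default=0.001, ge=0, lt=1)
    pcr_bias_sd: float = Field(default=0.5, ge=0)
    rc_fraction: float = Field(default=0.0, ge=0, le=1)
    seed: int = 0

    @field_validator("moi_per_vector")
    @classmethod
    def _non_negative_moi(cls, v: dict[str, float]) -> dict[str, float]:
        for color, moi in v.items():
            if moi < 0:
                raise ValueError(f"negative MOI for vector {color!r}")
        return v


class CallConfig(BaseModel):
    min_count: int = Field(default=10, ge=1)
    max_distance: int = Field(default=1, ge=0)
    ratio: float = Field(default=2.0, ge=1)
    strict_signature: bool = True
    handle_rc: bool = False


class AnalyzeConfig(BaseModel):
    top_k: int = Field(default=10, ge=1)
    dominance_threshold: float = Field(default=0.10, gt=0, lt=1)


class RunConfig(BaseModel):
    """Parameters for a full design -> simulate -> call -> analyze run."""

    schema_version: int = SCHEMA_VERSION
    sample_name: str = "sample"
    design: DesignConfig = DesignConfig()
    simulate: SimulateConfig = SimulateConfig()
    call: CallConfig = CallConfig()
    analyze: AnalyzeConfig = AnalyzeConfig()

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
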