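"""Run configuration: every tunable of the pipeline in one validated block.

Unknown keys are rejected so silent typos cannot change an analysis, and
the full parameter set is echoed into the run manifest for provenance.
Configs load from TOML.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .mining import DEFAULT_MIN_REPEATS, MiningConfig
from .primers import M13_TAIL_DEFAULT, PrimerConstraints

__all__ = ["MiningParams", "PrimerParams", "StatsParams", "ClusterParams",
           "FingerprintParams", "RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MiningParams(_Strict):
    min_repeats: dict[int, int] = Field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_linker: int = 100
    include_mono: bool = False

    @field_validator("min_repeats")
    @classmethod
    def _lengths(cls, v: dict[int, int]) -> dict[int, int]:
        MiningConfig(min_repeats=v)  # reuse the dataclass validation
        return v

    def to_mining_config(self) -> MiningConfig:
        return MiningConfig(
            min_repeats=self.min_repeats,
            max_linker=self.max_linker,
            include_mono=self.include_mono,
        )


class PrimerParams(_Strict):
    length: tuple[int, int] = (18, 25)
    tm: tuple[float, float] = (57.0, 62.0)
    product_size: tuple[int, int] = (120, 400)
    gc: tuple[float, float] = (40.0, 60.0)
    flank_length: int = 200
    tm_method: str = "nn"
    m13_tail: str = M13_TAIL_DEFAULT

    def to_constraints(self) -> PrimerConstraints:
        return PrimerConstraints(
            length=self.length, tm=self.tm,
            product_size=self.product_size, gc=self.gc,
        )


class StatsParams(_Strict):
    unbiased_hs: bool = False
    report_decimals: int = 4


class ClusterParams(_Strict):
    coefficient: str = "sm"
    linkage: str = "upgma"


class FingerprintParams(_Strict):
    max_core_size: int = 3
    mode: str = "bands"


class RunConfig(_Strict):
    """Umbrella configuration for an end-to-end run."""

    fasta: str | None = None
    gff3: str | None = None
    genotypes: str | None = None
    populations: str | None = None
    seed: int = 0
    mining: MiningParams = Field(default_factory=MiningParams)
    primers: PrimerParams = Field(default_factory=PrimerParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    cluster: ClusterParams = Field(default_factory=ClusterParams)
    fingerprint: FingerprintParams = Field(default_factory=FingerprintParams)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "mining" in data and "min_repeats" in data["mining"]:
        data["mining"]["min_repeats"] = {
            int(k): int(v) for k, v in data["mining"]["min_repeats"].items()
        }
    return RunConfig.model_validate(data)
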