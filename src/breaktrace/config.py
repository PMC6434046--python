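"""Run configuration: one YAML file carrying every figure-facing knob."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .hotspots import PeakParams
from .junctions import BaitConfig
from .preprocess import AdapterSpec, ConfigError

__all__ = ["DedupParams", "CallParams", "RunConfig", "load_config"]


@dataclass(frozen=True)
class DedupParams:
    max_edit: int = 2
    pos_tolerance: int = 2
    metric: str = "levenshtein"


@dataclass(frozen=True)
class CallParams:
    indel_window: int = 5
    proximal_span: int = 250_000
    min_prey_len: int = 20
    max_prey_edit_rate: float = 0.10
    min_mapq: int = 1


@dataclass
class RunConfig:
    genome_fasta: str
    bait: BaitConfig
    adapter: AdapterSpec
    sample_replicates: list[dict[str, str]]
    control: Optional[dict[str, str]] = None
    te: float = 1.0
    seed: int = 1
    output_dir: str = "breaktrace_out"
    dedup: DedupParams = field(default_factory=DedupParams)
    call: CallParams = field(default_factory=CallParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    allow_single_replicate: bool = False
    profile_window: int = 5000
    profile_binsize: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.te <= 1.0:
            raise ConfigError(f"transfection efficiency must be in (0, 1], got {self.te}")
        if not self.sample_replicates:
            raise ConfigError("at least one sample replicate is required")

    def validate_paths(self) -> None:
        missing = []
        if not Path(self.genome_fasta).exists():
            missing.append(self.genome_fasta)
        for rep in self.sample_replicates + ([self.control] if self.control else []):
            for key in ("r1", "r2"):
                if not Path(rep[key]).exists():
                    missing.append(rep[key])
        if missing:
            raise ConfigError(f"missing input files: {missing}")

    def echo(self) -> dict[str, Any]:
        """Plain-dict rendering for the run log (deterministic ordering)."""
        return {
            "genome_fasta": self.genome_fasta,
            "bait": vars(self.bait) | {},
            "adapter": {
                "sequencing_adapter": self.adapter.sequencing_adapter,
                "bridge_adapter_template": self.adapter.bridge_adapter_template,
                "bait_primer": self.adapter.bait_primer,
                "quality_floor": self.adapter.quality_floor,
            },
            "sample_replicates": self.sample_replicates,
            "control": self.control,
            "te": self.te,
            "seed": self.seed,
            "dedup": vars(self.dedup) | {},
            "call": vars(self.call) | {},
            "peaks": {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self.peaks).items()},
        }


def _sub(cls, data: dict[str, Any]):
    return cls(**data) if data else cls()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        bait = BaitConfig(**raw["bait"])
        adapter = AdapterSpec(**raw.get("adapter", {}))
        return RunConfig(
            genome_fasta=raw["genome_fasta"],
            bait=bait,
            adapter=adapter,
            sample_replicates=raw["sample_replicates"],
            control=raw.get("control"),
            te=raw.get("te", 1.0),
            seed=raw.get("seed", 1),
            output_dir=raw.get("output_dir", "breaktrace_out"),
            dedup=_sub(DedupParams, raw.get("dedup", {})),
            call=_sub(CallParams, raw.get("call", {})),
            peaks=_sub(PeakParams, {
                k: tuple(v) if isinstance(v, list) else v for k, v in raw.get("peaks", {}).items()
            }),
            allow_single_replicate=raw.get("allow_single_replicate", False),
            profile_window=raw.get("profile_window", 5000),
            profile_binsize=raw.get("profile_binsize", 50),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid run configuration {path}: {exc}") from exc
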