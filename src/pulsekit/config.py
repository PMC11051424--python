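"""Run configuration: one YAML file drives the whole pipeline.

A single root seed is split into per-stage seeds so stages rerun in isolation
reproduce the full run's outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .synth import ArtifactSpec, CohortDesign, DayEffect


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 61
    day0_fraction: float = 8.0 / 61.0
    day_effects: list = field(
        default_factory=lambda: [
            {"day_index": d, "hr_shift": 0.0, "hf_scale": 1.0, "amplitude_scale": 1.0}
            for d in range(5)
        ]
    )
    artifacts: dict = field(default_factory=dict)
    dropout_rate: float = 0.0
    tolerance_h: float = 4.0
    quality_threshold: float = 0.20
    spectral: dict = field(default_factory=dict)
    bootstrap_iterations: int = 10000
    output_dir: str = "runs/default"

    def stage_seed(self, stage: str) -> int:
        stages = ["simulate", "extract", "features", "compare"]
        seeds = np.random.SeedSequence(self.seed).spawn(len(stages))
        return int(seeds[stages.index(stage)].generate_state(1)[0])

    def cohort_design(self) -> CohortDesign:
        effects = tuple(DayEffect(**e) for e in self.day_effects)
        artifacts = ArtifactSpec(**self.artifacts) if self.artifacts else None
        return CohortDesign(
            n_participants=self.n_participants,
            day_effects=effects,
            day0_fraction=self.day0_fraction,
            artifacts=artifacts,
            dropout_rate=self.dropout_rate,
            seed=self.stage_seed("simulate"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
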