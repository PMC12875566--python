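"""Pipeline configuration with documented defaults.

Every setting defaults to the protocol's stated value where one exists:
gap filling up to 20 frames, harness fall threshold 0.30 x body weight,
100 Hz capture, fast speed = slow x 1.33.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic_data import SimulationParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "mostrip_out"
    max_gap: int = 20  # frames eligible for spline gap filling
    smoothing: str = "gcv"  # "gcv", "none", or a predicted MSE in m^2 as float
    boundary: str = "leading_toe"  # leading_toe | max_toe
    belt_mode: str = "instantaneous"  # instantaneous | nominal
    g: float = 9.81
    fall_threshold: float = 0.30  # fraction of body weight
    roc_pooling: str = "pooled"  # pooled | participant_mean
    pairing_unit: str = "perturbation"  # perturbation | participant
    seed: int = 0
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationParams(**self.simulation)
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML/JSON config file, applying keyword overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else (yaml.safe_load(text) or {})
        )
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
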