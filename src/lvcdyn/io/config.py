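"""Structured run configuration with YAML round trip."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..dynamics.settings import PropagationSettings

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Full-pipeline configuration.

    ``model`` is either a path to a model file or a manifold-spec mapping for
    the synthetic generator.  Every random operation carries its own seed.
    """

    model: dict = field(default_factory=lambda: {"preset": "small", "seed": 0})
    sampling: dict = field(default_factory=lambda: {"n": 100, "seed": 1})
    window: list = field(default_factory=lambda: [2.8, 3.2])
    selection_seed: int = 2
    propagation: dict = field(default_factory=lambda: PropagationSettings().to_dict())
    analysis: dict = field(
        default_factory=lambda: {
            "representation": "diabatic",
            "estimator": "mixed",
            "ct_threshold": 0.5,
            "coherence_thresholds": {},
        }
    )
    outdir: str = "lvcdyn_run"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def propagation_settings(self) -> PropagationSettings:
        return PropagationSettings.from_dict(self.propagation)


def load_config(path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
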