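"""Run configuration with the recommended defaults.

The three clustering thresholds default to the setting that is robust across
datasets: core density dens = 0.8, attachment density ε = 0.7, attachment
overlap θ = 0.5 (robust ranges dens ∈ [0.7, 0.9], ε ∈ [0.6, 0.8],
θ ∈ [0.4, 0.6]).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    dens: float = 0.8
    epsilon: float = 0.7
    theta: float = 0.5
    mu: float = 0.5
    dim: int = 64
    seed: int = 0
    max_levels: int = 5
    delta: float = 0.25
    train_mode: str = "off"
    epochs: int = 30

    def validate(self) -> None:
        for name in ("dens", "epsilon", "theta", "delta"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        if self.train_mode not in ("off", "reconstruction"):
            raise ValueError("train_mode must be 'off' or 'reconstruction'")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load keys from a YAML file; keyword overrides win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg
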