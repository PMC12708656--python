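"""Run configuration with lossless file round-tripping.

Configs are plain nested dicts behind a dataclass facade; they read from
TOML or JSON and write JSON.  Unknown keys are rejected so that typos never
pass silently.  All defaults equal the reference protocol values (n = 256,
dt = 1.8e-5 tau_r, burst D = 5e-4 for 1e-2 tau_r, R = 1, S = -1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .integrate import IntegratorConfig, NoiseSpec
from .model import ModelParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    n: int = 256
    A: float = 1000.0
    R: float = 1.0
    S: int = -1
    dt: float = 1.8e-5
    noise_D: float = 5e-4
    noise_duration: float = 1e-2
    t_final: float = 1.0
    diag_every: float = 1e-2
    snapshot_every: float = 0.1
    seed: int = 0
    protocol: str = "simulate"
    protocol_params: dict = field(default_factory=dict)
    out: str = "out"
    allow_underresolved: bool = False

    def model_params(self) -> ModelParams:
        return ModelParams(A=self.A, R=self.R, S=self.S)

    def integrator_config(self) -> IntegratorConfig:
        return IntegratorConfig(dt=self.dt)

    def noise_spec(self) -> NoiseSpec:
        return NoiseSpec(D=self.noise_D, duration=self.noise_duration,
                         seed=self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls.from_dict(d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
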