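"""Run configuration: defaults, JSON round-trip, validation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .dynamics import DEFAULT_ATOL, DEFAULT_RTOL, PERSISTENCE_THRESHOLD, STEADY_TOL, T_CAP
from .model import ModelParams, ModelVariant

__all__ = ["RunConfig", "load_config"]

_PARAM_FIELDS = ("k", "psi", "alpha", "beta", "omega", "upsilon", "tau", "gamma", "chi")


@dataclass
class RunConfig:
    """Effective configuration of a run; unset fields fall back to defaults."""

    # model parameters
    k: float = 1.0
    psi: float = 1.0
    alpha: float = 0.2
    beta: float = 0.9
    omega: float = 0.1
    upsilon: float = 0.0
    tau: float = 0.001
    gamma: float = 0.02
    chi: float = 1e-6
    variant: str = ModelVariant.NO_MUTATION.value
    # solver settings
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    steady_tol: float = STEADY_TOL
    t_cap: float = T_CAP
    persistence_threshold: float = PERSISTENCE_THRESHOLD
    # experiment settings
    t_end: float = 4000.0
    n_out: int = 2001
    n: int = 10000
    seed: int = 0
    antibiotic_levels: list[float] = field(default_factory=lambda: [0.0, 1e-3, 1e-2, 1e-1])
    outdir: str = "."

    def __post_init__(self) -> None:
        self.params()  # ModelParams enforces the parameter bounds
        ModelVariant(self.variant)
        for name in ("rtol", "atol", "steady_tol", "t_cap", "t_end", "persistence_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.n_out < 2:
            raise ValueError(f"n_out must be >= 2, got {self.n_out}")

    def params(self) -> ModelParams:
        """The model parameters described by this configuration."""
        kwargs = {name: getattr(self, name) for name in _PARAM_FIELDS}
        return ModelParams(variant=ModelVariant(self.variant), **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**d)


def load_config(path) -> RunConfig:
    """Read and validate a JSON configuration file."""
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path} must hold a JSON object of configuration keys")
    return RunConfig.from_dict(raw)
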