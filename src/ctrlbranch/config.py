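"""Scenario configuration: JSON schema (pydantic) and loading.

Schema::

    {
      "states": [
        {"label": "theta1",
         "offspring_pmf": {"0": 0.25, "1": 0.25, "2": 0.5},
         "alpha": 0.8,
         "control": {"kind": "identity"}}
      ],
      "probs": [1.0],
      "n0": 1,
      "seed": 42
    }

Control kinds: identity | binomial_thinning (p) | random_emigration
(removal_pmf) | random_immigration (addition_pmf) | tabulated (table).
Validation errors carry the JSON field path of the offending entry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, ValidationError, field_validator

from .environment import EnvironmentLaw, EnvironmentState
from .kernels import kernel_from_config

__all__ = ["ScenarioConfig", "ConfigError", "load_scenario", "law_from_config", "scenario_to_json"]


class ConfigError(ValueError):
    """Invalid scenario configuration; message carries the field path."""


class ControlConfig(BaseModel):
    kind: str
    p: float | None = None
    removal_pmf: dict[str, float] | None = None
    addition_pmf: dict[str, float] | None = None
    table: dict[str, dict[str, float]] | None = None
    k_analysis: int | None = None

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v):
        allowed = {"identity", "binomial_thinning", "random_emigration", "random_immigration", "tabulated"}
        if v not in allowed:
            raise ValueError(f"must be one of {sorted(allowed)}")
        return v


class StateConfig(BaseModel):
    label: str = Field(min_length=1)
    offspring_pmf: dict[str, float]
    alpha: float = Field(gt=0.0, le=1.0)
    control: ControlConfig
    eta: float | None = None  # optional dominator override


class ScenarioConfig(BaseModel):
    states: list[StateConfig] = Field(min_length=1)
    probs: list[float]
    n0: int = Field(ge=1, default=1)
    seed: int | None = None


def _pmf_array(mapping: dict[str, float], path: str) -> np.ndarray:
    try:
        keys = {int(k): float(v) for k, v in mapping.items()}
    except ValueError as exc:
        raise ConfigError(f"{path}: pmf keys must be non-negative integers ({exc})") from None
    if not keys or min(keys) < 0:
        raise ConfigError(f"{path}: pmf support must be non-empty, non-negative integers")
    out = np.zeros(max(keys) + 1)
    for k, v in keys.items():
        out[k] = v
    return out


def law_from_config(cfg: ScenarioConfig) -> EnvironmentLaw:
    states = []
    for i, sc in enumerate(cfg.states):
        control_cfg = sc.control.model_dump(exclude_none=True)
        try:
            kernel = kernel_from_config(control_cfg)
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"states.{i}.control: {exc}") from None
        try:
            states.append(
                EnvironmentState(
                    label=sc.label,
                    offspring_pmf=_pmf_array(sc.offspring_pmf, f"states.{i}.offspring_pmf"),
                    alpha=sc.alpha,
                    control=kernel,
                    eta_override=sc.eta,
                )
            )
        except ValueError as exc:
            raise ConfigError(f"states.{i}: {exc}") from None
    try:
        return EnvironmentLaw(states=states, probs=np.asarray(cfg.probs, dtype=float))
    except ValueError as exc:
        raise ConfigError(f"probs: {exc}") from None


def load_scenario(source) -> tuple[EnvironmentLaw, ScenarioConfig]:
    """Load a scenario from a path, JSON string, or dict; returns (law, config)."""
    if isinstance(source, (str, Path)) and Path(source).exists():
        raw = json.loads(Path(source).read_text())
    elif isinstance(source, str):
        raw = json.loads(source)
    else:
        raw = source
    try:
        cfg = ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        path = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"{path}: {first['msg']}") from None
    return law_from_config(cfg), cfg


def scenario_to_json(law: EnvironmentLaw, n0: int = 1, seed: int | None = None) -> dict:
    """Serialize a law back to the scenario JSON dialect."""
    return {
        "states": [
            {
                "label": st.label,
                "offspring_pmf": {str(r): float(p) for r, p in enumerate(st.offspring_pmf) if p > 0},
                "alpha": float(st.alpha),
                "control": st.control.to_config(),
            }
            for st in law.states
        ],
        "probs": [float(p) for p in law.probs],
        "n0": int(n0),
        "seed": seed,
    }
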