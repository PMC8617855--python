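"""Validated run configurations for the command-line interface.

A ``RunConfig`` is a schema-checked description of one command invocation
(samplesize, power, test, simulate, or table).  Validation re-checks every
design invariant with an actionable message and rejects unknown keys, so a
typo in a YAML config fails loudly instead of silently using a default.
When both a scalar compound-correlation target and explicit components are
given, the components win and a warning is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import yaml

from .correlations import ComponentCorrelations1, ComponentCorrelations2

__all__ = ["RunConfig", "validate_config", "load_config"]

COMMANDS = ("samplesize", "power", "test", "simulate", "table")

_KEYS = {
    "samplesize": {"objective", "alpha", "power", "m", "rate", "delta", "rho",
                   "components"},
    "power": {"objective", "alpha", "power", "m", "rate", "delta", "rho",
              "components", "n"},
    "test": {"objective", "alpha", "delta", "data", "dialect", "classification",
             "variance_flavor"},
    "simulate": {"objective", "n", "m", "rate", "rate2", "rho", "components",
                 "seed", "out"},
    "table": {"objective", "reps", "seed", "out", "cells"},
}

_COMP_KEYS1 = {"rho_r1", "rho_r2", "rho_s1", "rho_s2", "rho_ss"}
_COMP_KEYS2 = {"rho_xx", "rho_yy", "rho_xy"}


@dataclass(frozen=True)
class RunConfig:
    command: str
    parameters: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.parameters[key]

    def get(self, key, default=None):
        return self.parameters.get(key, default)


def _parse_components(raw: dict, objective: int, m: int):
    keys = set(raw) - {"m"}
    if objective == 1:
        if keys != _COMP_KEYS1:
            raise ValueError(
                f"objective-1 components must have exactly keys "
                f"{sorted(_COMP_KEYS1)}, got {sorted(keys)}"
            )
        return ComponentCorrelations1(m=raw.get("m", m), **{k: raw[k] for k in keys})
    if keys != _COMP_KEYS2:
        raise ValueError(
            f"objective-2 components must have exactly keys "
            f"{sorted(_COMP_KEYS2)}, got {sorted(keys)}"
        )
    return ComponentCorrelations2(m=raw.get("m", m), **{k: raw[k] for k in keys})


def validate_config(raw: dict) -> RunConfig:
    """Schema-check a raw config dict into a :class:`RunConfig`."""
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    command = raw.get("command")
    if command not in COMMANDS:
        raise ValueError(f"command must be one of {COMMANDS}, got {command!r}")
    params = {k: v for k, v in raw.items() if k != "command"}
    unknown = set(params) - _KEYS[command]
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} for command {command!r}; "
            f"allowed: {sorted(_KEYS[command])}"
        )

    objective = params.get("objective")
    if command != "table" and objective not in (1, 2):
        raise ValueError(f"objective must be 1 or 2, got {objective!r}")

    alpha = params.get("alpha", 0.05)
    if not 0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")

    if command in ("samplesize", "power"):
        rate, delta = params.get("rate"), params.get("delta")
        power = params.get("power", 0.8)
        if rate is None or not 0 < rate < 1:
            raise ValueError(f"concordance rate must be in (0, 1), got {rate}")
        if delta is None or delta <= 0:
            raise ValueError(
                "similarity margin / design difference must be positive, "
                f"got {delta}"
            )
        if delta >= rate:
            raise ValueError(f"need delta < rate, got delta={delta}, rate={rate}")
        if not 0.5 < power < 1:
            raise ValueError(f"target power must be in (0.5, 1), got {power}")
        if params.get("rho") is None and params.get("components") is None:
            raise ValueError("give either rho (compound target) or components")
        if params.get("rho") is not None and params.get("components") is not None:
            warnings.warn(
                "both rho and components given; components take precedence",
                stacklevel=2,
            )
        if command == "power" and (params.get("n") is None or params["n"] < 1):
            raise ValueError(f"power command needs n >= 1, got {params.get('n')}")

    if command == "simulate":
        if params.get("n", 0) < 1:
            raise ValueError(f"simulate needs n >= 1, got {params.get('n')}")
        if params.get("rho") is None and params.get("components") is None:
            raise ValueError("give either rho (compound target) or components")

    if command == "table":
        if params.get("objective") not in (1, 2):
            raise ValueError("table command needs objective 1 or 2")
        if params.get("reps", 10_000) < 100:
            raise ValueError(f"need reps >= 100, got {params.get('reps')}")

    if command == "test":
        if params.get("dialect", "readings") not in ("readings", "indicators"):
            raise ValueError(
                f"dialect must be 'readings' or 'indicators', "
                f"got {params.get('dialect')!r}"
            )
        if objective == 1:
            d1 = params.get("delta")
            if d1 is None or d1 <= 0:
                raise ValueError(
                    f"similarity margin must be positive, got {d1}"
                )

    if isinstance(params.get("components"), dict):
        m = params.get("m", 10 if objective == 1 else 5)
        params["components"] = _parse_components(params["components"], objective, m)
    return RunConfig(command=command, parameters=params)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
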