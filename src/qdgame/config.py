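"""TOML run configuration with a validated schema.

Sections: ``[model]`` (lop_order, tau, max_predictors), ``[test]`` (n_perm,
level), ``[optim]`` (starts, ftol, maxiter).  Unknown sections or keys fail
fast naming the offender; CLI flags override configuration values.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

SCHEMA = {
    "model": {"lop_order": int, "tau": float, "max_predictors": int},
    "test": {"n_perm": int, "level": float},
    "optim": {"starts": int, "ftol": float, "maxiter": int},
}


@dataclass
class RunConfig:
    lop_order: int = 3
    tau: float = 0.05
    max_predictors: int = 3
    n_perm: int = 1000
    level: float = 0.05
    starts: int = 5
    ftol: float = 1e-8
    maxiter: int = 2000
    extras: dict = field(default_factory=dict)


def load_config(path: str | Path | None) -> RunConfig:
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for section, entries in data.items():
        if section not in SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        for key, value in entries.items():
            if key not in SCHEMA[section]:
                raise ValueError(f"unknown config key [{section}].{key}")
            want = SCHEMA[section][key]
            if want is float and isinstance(value, int):
                value = float(value)
            if not isinstance(value, want):
                raise ValueError(f"config key [{section}].{key} must be {want.__name__}")
            setattr(cfg, key, value)
    return cfg
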