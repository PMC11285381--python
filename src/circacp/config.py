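"""Run configuration: every tunable of the detection pipeline in one place.

Precedence when running the CLI: command-line flag > YAML file > built-in
default. Unknown keys in a YAML file are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ContractError


@dataclass
class RunConfig:
    # cosinor
    period_min: float = 1440.0
    lower_fraction: float = 0.18
    cosinor_init: tuple = (500.0, 550.0, 227.0)
    cosinor_solver: str = "linear"
    # change point
    cp_lambda: float = 50.0
    cp_eps: float = 0.1
    cp_min_seg: int = 30
    cp_min_window: int = 240
    refine: bool = True
    # screening
    min_total_min: float = 5760.0
    min_period_min: float = 5760.0
    max_zero_run_min: float = 120.0
    enforce_screening: bool = True
    # qc / validation
    ch_delta_threshold: float = 100.0
    marker_window_min: float = 180.0
    sot_rollover_cut_min: float = 720.0

    # YAML aliases use the module-scoped dotted names
    _ALIASES = {
        "cosinor.period_min": "period_min",
        "cosinor.lower_fraction": "lower_fraction",
        "cosinor.init": "cosinor_init",
        "cosinor.solver": "cosinor_solver",
        "cp.lambda": "cp_lambda",
        "cp.eps": "cp_eps",
        "cp.min_seg": "cp_min_seg",
        "cp.min_window": "cp_min_window",
        "qc.ch_delta_threshold": "ch_delta_threshold",
        "validation.window_min": "marker_window_min",
        "validation.sot_rollover_cut_min": "sot_rollover_cut_min",
    }

    @classmethod
    def field_names(cls):
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = cls.field_names()
        kwargs = {}
        for key, val in d.items():
            name = cls._ALIASES.get(key, key)
            if name not in known:
                raise ContractError(f"unknown config key {key!r}")
            if name == "cosinor_init":
                val = tuple(float(v) for v in val)
            kwargs[name] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ContractError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cosinor_init"] = list(self.cosinor_init)
        return d
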