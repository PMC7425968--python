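"""Config-file plumbing: YAML/JSON parameter files -> ModelParams/SimConfig."""

from __future__ import annotations

from pathlib import Path

import yaml

from .dynamics import DemographyParams
from .migration import MigrationParams
from .simulator import ModelParams, SimConfig

__all__ = ["DEFAULT_CONFIG", "load_config", "config_to_dict"]

DEFAULT_CONFIG = {
    "r_d": 0.01,
    "v_r": 1.0,
    "spacecor": 0.0,
    "ceiling": 1.0,
    "k_volume": 17.0,
    "alpha": 0.01,
    "beta": 0.01,
    "tmax": 101,
    "trials": 500,
    "seed": 0,
    "n0_rule": "carrying_capacity",
}


def load_config(path=None, **overrides) -> tuple[ModelParams, SimConfig]:
    """Read a YAML/JSON config (all keys optional; defaults above).

    Keyword overrides win over the file, which wins over the defaults —
    handy for CLI --seed flags.
    """
    values = dict(DEFAULT_CONFIG)
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping of parameter: value")
        unknown = set(raw) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    params = ModelParams(
        demography=DemographyParams(
            r_d=float(values["r_d"]),
            v_r=float(values["v_r"]),
            spacecor=float(values["spacecor"]),
            ceiling=None if values["ceiling"] is None else float(values["ceiling"]),
        ),
        migration=MigrationParams(
            alpha=float(values["alpha"]), beta=float(values["beta"])
        ),
        k_volume=float(values["k_volume"]),
    )
    config = SimConfig(
        tmax=int(values["tmax"]),
        trials=int(values["trials"]),
        seed=int(values["seed"]),
        n0_rule=str(values["n0_rule"]),
    )
    return params, config


def config_to_dict(params: ModelParams, config: SimConfig) -> dict:
    """Flat dict echo of a parameter set (for run logs)."""
    return {
        "r_d": params.demography.r_d,
        "v_r": params.demography.v_r,
        "spacecor": params.demography.spacecor,
        "ceiling": params.demography.ceiling,
        "k_volume": params.k_volume,
        "alpha": params.migration.alpha,
        "beta": params.migration.beta,
        "tmax": config.tmax,
        "trials": config.trials,
        "seed": config.seed,
        "n0_rule": config.n0_rule,
    }
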