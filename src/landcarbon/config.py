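"""YAML configuration for the synthetic-ensemble pipeline."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .toymodel import (
    DEFAULT_FLAG_PROBS,
    DEFAULT_PARAM_RANGES,
    ForcingSet,
    generate_forcing,
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "n_models": 18,
    "window": [1958, 2020],
    "ref_year": 1959,
    "end_year": 2020,
    "regions": {"north": 0.4, "south": 0.6},
    "forcing": {
        "years": [1901, 2020],
        "co2": {"co2_ref": 280.0, "co2_end": 415.0},
        "climate": {"onset_year": 1921, "slope": 0.01, "sigma": 0.1},
        "lulcc": {"anchors": {1901: 0.15, 1960: 0.25, 2020: 0.30}},
    },
    "parameter_ranges": {k: list(v) for k, v in DEFAULT_PARAM_RANGES.items()},
    "flag_probabilities": dict(DEFAULT_FLAG_PROBS),
}


def default_config() -> dict[str, Any]:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults, overlaid with the YAML file at ``path`` if given."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def forcing_from_config(cfg: Mapping[str, Any], seed: int | None = None) -> ForcingSet:
    fc = cfg["forcing"]
    y0, y1 = fc["years"]
    lulcc = dict(fc.get("lulcc", {}))
    if "anchors" in lulcc:
        lulcc["anchors"] = {int(k): float(v) for k, v in lulcc["anchors"].items()}
    return generate_forcing(
        range(int(y0), int(y1) + 1),
        co2_spec=fc.get("co2"),
        climate_spec=fc.get("climate"),
        lulcc_spec=lulcc,
        seed=cfg["seed"] if seed is None else seed,
    )


def ensemble_kwargs(cfg: Mapping[str, Any], seed: int | None = None) -> dict[str, Any]:
    """Keyword arguments for :func:`landcarbon.toymodel.generate_ensemble`."""
    ranges = {k: tuple(v) for k, v in cfg["parameter_ranges"].items()}
    return {
        "n_models": int(cfg["n_models"]),
        "forcing": forcing_from_config(cfg, seed),
        "parameter_ranges": ranges,
        "flag_probabilities": dict(cfg["flag_probabilities"]),
        "seed": cfg["seed"] if seed is None else seed,
        "window": tuple(cfg["window"]),
        "region_weights": dict(cfg["regions"]) or None,
    }
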