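"""Declarative YAML configuration shared by the CLI subcommands.

Sections:

    truth:   PopulationParameters fields for the generating model
    design:  CohortConfig fields (cohort sizes, demographics, dosing, AE link)
    fit:     FitConfig fields (tolerances, starts, error model, fixed params)
    ae:      exposure-AE options (metric, outcome)

Every section is optional; omitted fields keep the package defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .estimate import FitConfig
from .model import PopulationParameters
from .simulate import CohortConfig


def load_config(path=None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"truth", "design", "fit", "ae"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return data


def _build(cls, section: dict, **overrides):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**{**section, **overrides})


def truth_from_config(cfg: dict) -> PopulationParameters:
    return _build(PopulationParameters, cfg.get("truth", {}))


def cohort_from_config(cfg: dict, seed: int | None = None) -> CohortConfig:
    over = {"truth": truth_from_config(cfg)}
    if seed is not None:
        over["seed"] = seed
    return _build(CohortConfig, cfg.get("design", {}), **over)


def fit_from_config(cfg: dict, init: PopulationParameters | None = None,
                    seed: int | None = None) -> FitConfig:
    section = dict(cfg.get("fit", {}))
    if "fix" in section:
        section["fix"] = tuple(section["fix"])
    over = {}
    if init is not None:
        over["init"] = init
    if seed is not None:
        over["seed"] = seed
    return _build(FitConfig, section, **over)


def ae_options(cfg: dict) -> dict:
    section = dict(cfg.get("ae", {}))
    section.setdefault("metric", "trough")
    section.setdefault("outcome", "DRAE")
    if section["metric"] not in ("trough", "auc"):
        raise ValueError("ae.metric must be 'trough' or 'auc'")
    if section["outcome"] not in ("DRAE", "DIZZINESS"):
        raise ValueError("ae.outcome must be 'DRAE' or 'DIZZINESS'")
    return section


def write_example_config(path) -> None:
    example = {
        "truth": {"theta1_cl": 1.65, "theta2_wt_cl": 0.67, "theta3_v": 59.0,
                  "theta4_wt_v": 0.96, "ka": 0.34},
        "design": {"n_sparse": 447, "n_rich": 40},
        "fit": {"n_starts": 3, "error_model": "proportional"},
        "ae": {"metric": "trough", "outcome": "DRAE"},
    }
    Path(path).write_text(yaml.safe_dump(example, sort_keys=False))


__all__ = [
    "load_config",
    "truth_from_config",
    "cohort_from_config",
    "fit_from_config",
    "ae_options",
    "write_example_config",
]
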