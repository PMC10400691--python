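"""YAML configuration loading and validation.

An empty (or absent) file yields the study defaults: R = 10 000, T = 3,
B = 60, d = 70, w = 10, s = 0.7, e = 1, all six policies, the five reference
comorbidities with calibrated prevalence weights.  Unknown keys are rejected
with field-level messages; infeasible combinations (e.g. d < B with an
ex-ante policy requested) fail at load time.
"""

from __future__ import annotations

from typing import Any, Mapping, Optional

import yaml

from .distributions import RiskScaling, TriangularParams
from .engine import ExperimentConfig
from .population import (
    CATEGORY_DISABILITY,
    CATEGORY_PRE_EXISTING,
    BASELINE_TRIANGLE,
    ComorbidityProfile,
    PopulationMix,
    calibrate_prevalence_weights,
    default_population_mix,
    reference_comorbidities,
)

__all__ = ["ConfigError", "load_config", "config_from_dict", "config_to_dict"]

_TOP_KEYS = {
    "replications",
    "horizon",
    "beds",
    "initial_demand",
    "queue_length",
    "comorbid_share",
    "misestimation",
    "policies",
    "seed",
    "random_init_from_demand",
    "population",
}
_POP_KEYS = {"disability_share", "baseline", "single_condition", "calibrated", "comorbidities"}
_COMORBIDITY_KEYS = {
    "name",
    "category",
    "relative_risk",
    "method",
    "triangle",
    "widen",
    "prevalence_weight",
}
_TRIANGLE_KEYS = {"minimum", "maximum", "mode"}


class ConfigError(ValueError):
    """Raised for schema violations, with the offending field in the message."""


def _check_keys(mapping: Mapping[str, Any], allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _triangle(raw: Mapping[str, Any], context: str) -> TriangularParams:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{context}: triangle must be a mapping with {sorted(_TRIANGLE_KEYS)}")
    _check_keys(raw, _TRIANGLE_KEYS, context)
    missing = _TRIANGLE_KEYS - set(raw)
    if missing:
        raise ConfigError(f"{context}: triangle missing {sorted(missing)}")
    try:
        return TriangularParams(
            minimum=float(raw["minimum"]),
            maximum=float(raw["maximum"]),
            mode=float(raw["mode"]),
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{context}: {err}") from err


def _profile(raw: Mapping[str, Any], index: int) -> ComorbidityProfile:
    context = f"population.comorbidities[{index}]"
    _check_keys(raw, _COMORBIDITY_KEYS, context)
    for key in ("name", "category", "relative_risk", "prevalence_weight"):
        if key not in raw:
            raise ConfigError(f"{context}: missing required key {key!r}")
    explicit = _triangle(raw["triangle"], context) if "triangle" in raw else None
    method = raw.get("method", "explicit" if explicit is not None else "translate")
    try:
        scaling = RiskScaling(
            relative_risk=float(raw["relative_risk"]),
            method=method,
            explicit=explicit,
            widen=float(raw.get("widen", 0.0)),
        )
        return ComorbidityProfile(
            name=str(raw["name"]),
            category=str(raw["category"]),
            scaling=scaling,
            prevalence_weight=float(raw["prevalence_weight"]),
        )
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{context}: {err}") from err


def _population(raw: Mapping[str, Any], comorbid_share: float) -> PopulationMix:
    _check_keys(raw, _POP_KEYS, "population")
    baseline = (
        _triangle(raw["baseline"], "population.baseline")
        if "baseline" in raw
        else BASELINE_TRIANGLE
    )
    disability_share = float(raw.get("disability_share", 0.1))
    if "comorbidities" in raw:
        entries = raw["comorbidities"]
        if not isinstance(entries, list) or not entries:
            raise ConfigError("population.comorbidities must be a non-empty list")
        profiles = tuple(_profile(entry, i) for i, entry in enumerate(entries))
    else:
        profiles = reference_comorbidities()
    if raw.get("calibrated", "comorbidities" not in raw):
        profiles = calibrate_prevalence_weights(
            profiles, base=baseline, disability_share=disability_share
        )
    try:
        return PopulationMix(
            share_comorbid=comorbid_share,
            disability_share=disability_share,
            profiles=profiles,
            baseline=baseline,
            single_condition=raw.get("single_condition"),
        )
    except ValueError as err:
        raise ConfigError(f"population: {err}") from err


def config_from_dict(raw: Optional[Mapping[str, Any]]) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from a parsed mapping."""
    raw = dict(raw or {})
    _check_keys(raw, _TOP_KEYS, "config")
    kwargs: dict[str, Any] = {}
    scalars = {
        "replications": int,
        "horizon": int,
        "beds": int,
        "initial_demand": int,
        "queue_length": int,
        "comorbid_share": float,
        "misestimation": float,
        "random_init_from_demand": bool,
    }
    for key, cast in scalars.items():
        if key in raw:
            try:
                kwargs[key] = cast(raw[key])
            except (TypeError, ValueError) as err:
                raise ConfigError(f"config.{key}: {err}") from err
    if "seed" in raw:
        kwargs["master_seed"] = int(raw["seed"])
    if "policies" in raw:
        policies = raw["policies"]
        if not isinstance(policies, (list, tuple)):
            raise ConfigError("config.policies must be a list of policy ids 0-5")
        kwargs["policies"] = tuple(int(p) for p in policies)
    if "population" in raw:
        if not isinstance(raw["population"], Mapping):
            raise ConfigError("config.population must be a mapping")
        share = kwargs.get("comorbid_share", 0.7)
        kwargs["mix"] = _population(raw["population"], share)
    try:
        return ExperimentConfig(**kwargs)
    except ValueError as err:
        raise ConfigError(str(err)) from err


def load_config(path: Optional[str]) -> ExperimentConfig:
    """Load a YAML config file; ``None`` or an empty file gives the defaults."""
    if path is None:
        return ExperimentConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def config_to_dict(config: ExperimentConfig) -> dict[str, Any]:
    """Serialize a config (with its fully resolved population) to primitives."""
    mix = config.resolved_mix
    return {
        "replications": config.replications,
        "horizon": config.horizon,
        "beds": config.beds,
        "initial_demand": config.initial_demand,
        "queue_length": config.queue_length,
        "comorbid_share": config.comorbid_share,
        "misestimation": config.misestimation,
        "policies": list(config.policies),
        "seed": config.master_seed,
        "random_init_from_demand": config.random_init_from_demand,
        "population": {
            "disability_share": mix.disability_share,
            "single_condition": mix.single_condition,
            "calibrated": False,  # weights below are already final
            "baseline": {
                "minimum": mix.baseline.minimum,
                "maximum": mix.baseline.maximum,
                "mode": mix.baseline.mode,
            },
            "comorbidities": [
                {
                    "name": p.name,
                    "category": p.category,
                    "relative_risk": p.scaling.relative_risk,
                    "method": p.scaling.method,
                    **(
                        {
                            "triangle": {
                                "minimum": p.scaling.explicit.minimum,
                                "maximum": p.scaling.explicit.maximum,
                                "mode": p.scaling.explicit.mode,
                            }
                        }
                        if p.scaling.explicit is not None
                        else {}
                    ),
                    "widen": p.scaling.widen,
                    "prevalence_weight": p.prevalence_weight,
                }
                for p in mix.profiles
            ],
        },
    }
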