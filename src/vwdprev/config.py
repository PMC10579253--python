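"""Configuration loading: population specs and prevalence study settings."""

from __future__ import annotations

from importlib import resources
from typing import Optional

import yaml

from vwdprev.cohort import PopulationLabel
from vwdprev.prevalence import PrevalenceConfig

__all__ = ["default_prevalence_config", "load_population_config", "prevalence_config_from_dict"]


def load_population_config(path: str) -> tuple[PopulationLabel, ...]:
    """Load a population spec YAML: ``populations: [{code, name, n_individuals}]``."""
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    if not payload or "populations" not in payload:
        raise ValueError(f"{path}: expected a 'populations' list")
    pops = tuple(
        PopulationLabel(code=str(p["code"]), display_name=str(p.get("name", p["code"])), n_individuals=int(p["n_individuals"]))
        for p in payload["populations"]
    )
    codes = [p.code for p in pops]
    if len(codes) != len(set(codes)):
        raise ValueError(f"{path}: duplicate population codes")
    return pops


def prevalence_config_from_dict(payload: dict) -> PrevalenceConfig:
    exclusions = payload.get("exclusions", {}) or {}
    type_exclusions = payload.get("type_exclusions", {}) or {}
    return PrevalenceConfig(
        exclusions_global=tuple(exclusions.get("global", ()) or ()),
        exclusions_by_population={
            code: tuple(names) for code, names in (exclusions.get("by_population", {}) or {}).items()
        },
        type_exclusions_by_population={
            code: tuple(names) for code, names in (type_exclusions.get("by_population", {}) or {}).items()
        },
        type_maf_cutoff=payload.get("type_maf_cutoff", 0.01),
        scale=payload.get("scale", "per100"),
        type_scale=payload.get("type_scale", "per1000"),
    )


def default_prevalence_config() -> PrevalenceConfig:
    """The shipped study defaults (common-variant exclusions, 1% type cutoff)."""
    text = resources.files("vwdprev").joinpath("data/default_config.yaml").read_text()
    return prevalence_config_from_dict(yaml.safe_load(text))


def load_prevalence_config(path: Optional[str]) -> PrevalenceConfig:
    if path is None:
        return default_prevalence_config()
    with open(path) as handle:
        return prevalence_config_from_dict(yaml.safe_load(handle) or {})
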