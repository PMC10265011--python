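"""Pipeline configuration: one YAML/JSON file covering every stage.

Sections map one-to-one onto the dataclasses they configure::

    beliefs:     -> games.BeliefConfig
    priors:      -> inference.PriorSpec
    mcmc:        -> inference.McmcConfig
    simulation:  -> simulate.SimulationConfig (minus nested specs, which use
                    dotted keys, e.g. beta_truth: {loc, scale, lower, upper})
    association: -> options passed to genetics.ancova

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .errors import ConfigurationError
from .games import BeliefConfig
from .inference import McmcConfig, PriorSpec
from .simulate import LogNormalSpec, SimulationConfig, TruncNormalSpec


@dataclass(frozen=True)
class AssociationOptions:
    dependents: tuple[str, ...] = ("alpha_mean", "beta_mean")
    covariates: tuple[str, ...] = ("age",)
    sex_interactions: bool = False
    carrier_coding: bool = False  # use the 334 bp carrier factor instead of SS/SL/LL


@dataclass(frozen=True)
class PipelineConfig:
    beliefs: BeliefConfig = BeliefConfig()
    priors: PriorSpec = PriorSpec()
    mcmc: McmcConfig = McmcConfig()
    simulation: SimulationConfig = SimulationConfig()
    association: AssociationOptions = AssociationOptions()

    def hash(self) -> str:
        """Short stable digest of the full configuration, for run logs."""
        blob = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _as_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _build(cls, section: dict, name: str, nested: Optional[dict] = None):
    nested = nested or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(
            f"unknown keys in config section {name!r}: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in section.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = nested[key](**value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: Optional[Path] = None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load a pipeline config from YAML/JSON; missing sections use defaults.

    ``overrides`` is a {section: {key: value}} mapping applied on top (used
    by the CLI for --seed and friends).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
    for section, kv in (overrides or {}).items():
        raw.setdefault(section, {})
        raw[section] = {**raw[section], **kv}

    known_sections = {"beliefs", "priors", "mcmc", "simulation", "association"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    sim_nested = {
        "alpha_truth": TruncNormalSpec,
        "beta_truth": TruncNormalSpec,
        "lambda_truth": LogNormalSpec,
        "beliefs": BeliefConfig,
    }
    return PipelineConfig(
        beliefs=_build(BeliefConfig, raw.get("beliefs", {}), "beliefs"),
        priors=_build(PriorSpec, raw.get("priors", {}), "priors"),
        mcmc=_build(McmcConfig, raw.get("mcmc", {}), "mcmc"),
        simulation=_build(
            SimulationConfig, raw.get("simulation", {}), "simulation", sim_nested
        ),
        association=_build(
            AssociationOptions, raw.get("association", {}), "association"
        ),
    )
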