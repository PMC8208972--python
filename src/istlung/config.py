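"""YAML/JSON configuration for simulator and inversion runs.

A config document is a flat nested mapping; every key is optional and falls
back to the package default, e.g.::

    settings:
      tidal_volume: 0.5
      respiratory_rate: 12
      ie_ratio: 0.5
      dead_space: 0.15
    forcing:
      period: 180
      mean_fraction: 0.04
      amplitude_fraction: 0.02
      phase: 0.0
    theta:
      v_a: 2.3
      q_p: 4.9
      mu_v: 1.0
      sigma_v: 0.3
      mu_p: 1.0
      sigma_p: 0.5
    lung:
      n_alv: 125
      n_ds: 10
    body:
      tissue_volumes: [6.0, 33.0, 14.5, 12.0, 5.0]
      flow_fractions: [0.75, 0.18, 0.05, 0.02, 0.0]
      tissue_blood_partition: [1.0, 1.0, 2.3, 1.0, 1.0]
      blood_gas_partition: 0.47
    optimizer:
      method: bayes
      n_iterations: 200
      seed: 0
      bounds:
        sigma_v: [0.01, 2.0]
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

from .inversion import OptimizerConfig
from .simulator import (
    BodyCompartmentSet,
    LognormalSpec,
    SinewaveForcing,
    ThetaParams,
    VentilatorSettings,
)

__all__ = ["SimulationConfig", "load_config"]


@dataclass
class SimulationConfig:
    """Bundle of all configurable objects for a simulation/inversion run."""

    settings: VentilatorSettings = field(default_factory=VentilatorSettings)
    forcing: SinewaveForcing | None = None
    theta: ThetaParams | None = None
    body: BodyCompartmentSet = field(default_factory=BodyCompartmentSet)
    n_alv: int = 125
    n_ds: int = 10
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)


def _settings_from(d: dict) -> VentilatorSettings:
    return VentilatorSettings(**d)


def _forcing_from(d: dict) -> SinewaveForcing:
    return SinewaveForcing(**d)


def _theta_from(d: dict) -> ThetaParams:
    return ThetaParams(
        v_a=float(d["v_a"]),
        q_p=float(d["q_p"]),
        vent=LognormalSpec(float(d.get("mu_v", 1.0)), float(d.get("sigma_v", 0.0))),
        perf=LognormalSpec(float(d.get("mu_p", 1.0)), float(d.get("sigma_p", 0.0))),
    )


def _optimizer_from(d: dict) -> OptimizerConfig:
    if "bounds" in d and d["bounds"] is not None:
        d = dict(d)
        d["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
    return OptimizerConfig(**d)


def load_config(path) -> SimulationConfig:
    """Load a YAML (``.yml``/``.yaml``) or JSON config document."""
    path = str(path)
    with open(path) as fh:
        raw = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    raw = raw or {}
    cfg = SimulationConfig()
    if "settings" in raw:
        cfg.settings = _settings_from(raw["settings"])
    if "forcing" in raw:
        cfg.forcing = _forcing_from(raw["forcing"])
    if "theta" in raw:
        cfg.theta = _theta_from(raw["theta"])
    if "body" in raw:
        cfg.body = BodyCompartmentSet(**raw["body"])
    lung = raw.get("lung", {})
    cfg.n_alv = int(lung.get("n_alv", 125))
    cfg.n_ds = int(lung.get("n_ds", 10))
    if "optimizer" in raw:
        cfg.optimizer = _optimizer_from(raw["optimizer"])
    return cfg
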