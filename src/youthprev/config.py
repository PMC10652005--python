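"""Scenario configuration files (YAML) and result serialization.

A scenario file holds nested blocks:

.. code-block:: yaml

    scenario: table1_baseline
    parameters:            # phi/theta required; rates optional (defaults used)
      phi: 0.4
      theta: 2.0
    targets:               # optional; defaults to the Australian estimates
      target_prev_D: 0.0780
      target_prev_S: 0.186
      target_population: 1000000
    interventions:         # optional
      - kind: universal
        effect: 0.21

Parsing validates against the parameter invariants and reports the first
failing one by name. Serialization is round-trip idempotent.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .interventions import InterventionSpec
from .params import DomainViolationError

__all__ = ["load_scenario", "dump_scenario", "scenario_interventions",
           "write_json", "write_csv"]


def load_scenario(path: str | Path) -> dict:
    """Parse and validate a scenario configuration file."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise DomainViolationError(f"{path}: expected a mapping at top level")
    if "parameters" not in config or not isinstance(config["parameters"], dict):
        raise DomainViolationError(f"{path}: missing 'parameters' block")
    p = config["parameters"]
    for required in ("phi", "theta"):
        if required not in p:
            raise DomainViolationError(f"{path}: parameters.{required} is required")
    # surface invariant violations early, naming the offending field
    from .model import PreventionModel  # deferred: avoid import cycle

    PreventionModel.from_config(config)
    for spec in scenario_interventions(config):
        _ = spec  # constructor validates
    return config


def scenario_interventions(config: dict) -> list[InterventionSpec]:
    return [
        InterventionSpec(kind=entry["kind"], effect=float(entry["effect"]))
        for entry in config.get("interventions", [])
    ]


def dump_scenario(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True, default_flow_style=False)


def write_json(data: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_csv(frame, path: str | Path) -> None:
    """Write a DataFrame with a fixed locale-independent numeric convention."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.12g")
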