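"""Packaged reference tables and default configurations.

* ``portugal_population`` — resident population of Portugal by district
  for 2018 and 2021 (official national statistics), the denominator of
  every DID and prevalence computation.
* ``national_did`` — published national antidiabetic consumption (DID)
  by ATC class for 2018 and 2021.
* ``ddd_registry`` — a synthetic DDD registry covering the A10
  formulary; working values for tests and demos, not the official WHO
  ATC/DDD index.
* ``base_params`` / ``scenario`` files — the base-case model parameters
  and the one-at-a-time sensitivity scenarios.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from ..atc import DDDRegistry

__all__ = [
    "dataset_path",
    "portugal_population",
    "national_did",
    "ddd_registry",
    "base_params_path",
    "scenarios_path",
]


def dataset_path(name: str) -> Path:
    """Filesystem path of a packaged dataset file."""
    path = resources.files(__package__).joinpath(name)
    return Path(str(path))


def portugal_population() -> pd.DataFrame:
    """Population by district and year (columns region, year, inhabitants)."""
    return pd.read_csv(dataset_path("portugal_population.csv"), comment="#")


def national_did() -> pd.DataFrame:
    """Published national consumption (columns atc_class, year, did)."""
    return pd.read_csv(dataset_path("national_did.csv"), comment="#")


def ddd_registry() -> DDDRegistry:
    """The synthetic A10 DDD registry."""
    return DDDRegistry.from_csv(dataset_path("ddd_registry_a10_synthetic.csv"))


def base_params_path() -> Path:
    return dataset_path("base_params.yaml")


def scenarios_path() -> Path:
    return dataset_path("sensitivity_scenarios.yaml")
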