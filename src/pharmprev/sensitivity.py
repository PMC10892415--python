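"""One-at-a-time sensitivity analysis over the prevalence model parameters.

Each scenario re-runs the full estimator with a single parameter (or, in
principle, a small set) replaced by an alternative literature value while
every other parameter stays at its base-case value.  The scenario table
keeps the base case as its first block so the deltas can be read off
directly; a tornado-style summary ranks parameters by the spread of the
outcome across their scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .model import ModelParams, run_model

__all__ = ["Scenario", "run_scenarios", "tornado_ranges", "BASE_SCENARIO"]

#: name reserved for the unmodified base-case row block
BASE_SCENARIO = "base"

SCENARIO_COLUMNS = ["scenario", "parameter", "value"]


@dataclass(frozen=True)
class Scenario:
    """A named set of parameter overrides applied one run at a time."""

    name: str
    overrides: Mapping[str, object]
    years: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.overrides:
            raise ValueError(f"scenario {self.name!r} has no overrides")
        if self.name == BASE_SCENARIO:
            raise ValueError(f"scenario name {BASE_SCENARIO!r} is reserved")

    @property
    def parameter(self) -> str:
        """Label of the varied parameter(s)."""
        return "+".join(sorted(self.overrides))


def _apply(params: "ModelParams | Mapping[int, ModelParams]", scenario: Scenario | None):
    if scenario is None:
        return params
    if isinstance(params, ModelParams):
        return params.replace(**dict(scenario.overrides))
    return {year: p.replace(**dict(scenario.overrides)) for year, p in params.items()}


def run_scenarios(
    consumption: pd.DataFrame,
    population: pd.DataFrame,
    base_params: "ModelParams | Mapping[int, ModelParams]",
    scenarios: Sequence[Scenario],
    *,
    scopes: list[str] | None = None,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Run the base case followed by each scenario.

    Returns the concatenated estimate rows with three leading columns:
    ``scenario`` (name, ``"base"`` first), ``parameter`` (varied key) and
    ``value`` (the override value).  Validation of override keys and ranges
    happens in :meth:`ModelParams.replace` before any model run.
    """
    blocks = []
    base = run_model(consumption, population, base_params, scopes=scopes, years=years)
    base = base.copy()
    base.insert(0, "scenario", BASE_SCENARIO)
    base.insert(1, "parameter", "")
    base.insert(2, "value", "")
    blocks.append(base)

    for scenario in scenarios:
        run_years = list(scenario.years) if scenario.years is not None else years
        result = run_model(
            consumption,
            population,
            _apply(base_params, scenario),
            scopes=scopes,
            years=run_years,
        )
        result = result.copy()
        result.insert(0, "scenario", scenario.name)
        result.insert(1, "parameter", scenario.parameter)
        result.insert(
            2, "value",
            "+".join(str(scenario.overrides[k]) for k in sorted(scenario.overrides)),
        )
        blocks.append(result)
    return pd.concat(blocks, ignore_index=True)


def tornado_ranges(
    table: pd.DataFrame,
    *,
    scope: str | None = None,
    year: int | None = None,
) -> pd.DataFrame:
    """Per-parameter outcome spread across the scenarios in ``table``.

    The outcome column is the overall prevalence for scenarios varying the
    undiagnosed fraction (only the overall estimate responds to it) and the
    treated prevalence otherwise.  The base-case outcome participates in
    every parameter's range, so a single scenario spans zero width only
    when it coincides with the base.  Rows are sorted by descending spread,
    ties broken alphabetically by parameter name.
    """
    rows = table
    if scope is not None:
        rows = rows[rows["scope"] == scope]
    if year is not None:
        rows = rows[rows["year"] == year]
    base_rows = rows[rows["scenario"] == BASE_SCENARIO]
    rows = rows[rows["scenario"] != BASE_SCENARIO]
    out = []
    for parameter, group in rows.groupby("parameter"):
        column = (
            "prev_overall_pct"
            if parameter == "undiagnosed_fraction"
            else "prev_treated_pct"
        )
        values = pd.concat([group[column], base_rows[column]])
        lo, hi = values.min(), values.max()
        out.append(
            {
                "parameter": parameter,
                "outcome": column,
                "min": lo,
                "max": hi,
                "spread": hi - lo,
            }
        )
    result = pd.DataFrame(out, columns=["parameter", "outcome", "min", "max", "spread"])
    return result.sort_values(
        ["spread", "parameter"], ascending=[False, True], ignore_index=True
    )
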