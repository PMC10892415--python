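"""Table readers/writers, parameter files, and report rendering.

All tables are UTF-8, comma-delimited, dot-decimal CSV with a mandatory
header row; lines starting with ``#`` are comments.  Validation failures
raise :class:`ValidationError` naming the offending file, column and row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .atc import ATCFormatError, DDDRegistry, validate_atc
from .consumption import (
    CONSUMPTION_COLUMNS,
    POPULATION_COLUMNS,
    RECORD_COLUMNS,
    TOTAL_LABEL,
)
from .model import ModelParams, round_half_up
from .sensitivity import Scenario

__all__ = [
    "ValidationError",
    "read_records",
    "read_population",
    "read_registry",
    "read_params",
    "read_scenarios",
    "read_cohort_config",
    "write_table",
    "render_consumption",
    "render_estimates",
    "render_scenarios",
]

logger = logging.getLogger(__name__)

#: canonical row order of the antidiabetic consumption report
A10_REPORT_ORDER = [
    "A10AB", "A10AC", "A10AD", "A10AE", "A10A",
    "A10BA", "A10BB", "A10BD", "A10BF", "A10BG",
    "A10BH", "A10BJ", "A10BK", "A10BX", "A10B",
]


class ValidationError(Exception):
    """An input file failed schema or invariant checks."""


def _read_csv(path: str | Path, columns: list[str], kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{kind} file not found: {path}")
    try:
        frame = pd.read_csv(path, comment="#", encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty {kind} file: {path}") from None
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: {kind} table missing column(s) {missing}")
    if frame.empty:
        raise ValidationError(f"{path}: {kind} table has a header but no rows")
    logger.info("read %d %s row(s) from %s", len(frame), kind, path)
    return frame


def read_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a dispensing-records table."""
    frame = _read_csv(path, RECORD_COLUMNS, "dispensing records")
    for i, code in frame["atc"].items():
        try:
            validate_atc(str(code))
        except ATCFormatError as exc:
            raise ValidationError(f"{path}, row {i + 2}, column 'atc': {exc}") from exc
    bad = frame.index[frame["n_units"].astype(float) < 0]
    if len(bad):
        raise ValidationError(f"{path}, row {bad[0] + 2}, column 'n_units': negative value")
    bad = frame.index[frame["strength"].astype(float) <= 0]
    if len(bad):
        raise ValidationError(f"{path}, row {bad[0] + 2}, column 'strength': non-positive value")
    return frame[RECORD_COLUMNS]


def read_population(path: str | Path) -> pd.DataFrame:
    """Read and validate a population table."""
    frame = _read_csv(path, POPULATION_COLUMNS, "population")
    bad = frame.index[frame["inhabitants"].astype(int) <= 0]
    if len(bad):
        raise ValidationError(
            f"{path}, row {bad[0] + 2}, column 'inhabitants': must be positive"
        )
    if frame.duplicated(["region", "year"]).any():
        dup = frame[frame.duplicated(["region", "year"])].iloc[0]
        raise ValidationError(
            f"{path}: duplicate population entry for ({dup['region']!r}, {dup['year']})"
        )
    return frame[POPULATION_COLUMNS]


def read_registry(path: str | Path) -> DDDRegistry:
    """Read a DDD registry CSV."""
    try:
        return DDDRegistry.from_csv(path)
    except (ValueError, OSError) as exc:
        raise ValidationError(str(exc)) from exc


def read_params(path: str | Path) -> "ModelParams | dict[int, ModelParams]":
    """Read a model-parameter file (flat YAML key-value mapping).

    Keys: ``adherence_nad, adherence_insulin, w`` *or* ``pi2, pi3, pi4``,
    ``insulin_t2dm_fraction, undiagnosed_fraction``.  Any value may instead
    be a ``{year: value}`` mapping, in which case a per-year parameter set
    is returned.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"parameter file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: parameter file must be a key-value mapping")
    if {"pi2", "pi3", "pi4"} & raw.keys():
        try:
            raw["pis"] = (raw.pop("pi2"), raw.pop("pi3"), raw.pop("pi4"))
        except KeyError as exc:
            raise ValidationError(f"{path}: pi2, pi3, pi4 must be given together") from exc
    years = sorted(
        {y for v in raw.values() if isinstance(v, dict) for y in v}
    )
    try:
        if not years:
            return ModelParams(**raw)
        return {
            int(year): ModelParams(
                **{
                    key: (value[year] if isinstance(value, dict) else value)
                    for key, value in raw.items()
                }
            )
            for year in years
        }
    except (TypeError, ValueError, KeyError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_scenarios(path: str | Path) -> list[Scenario]:
    """Read a scenario file: ``scenarios:`` list of named override blocks."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"scenario file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or not isinstance(raw.get("scenarios"), list):
        raise ValidationError(f"{path}: expected a top-level 'scenarios' list")
    scenarios = []
    for i, block in enumerate(raw["scenarios"]):
        if not isinstance(block, dict) or "name" not in block:
            raise ValidationError(f"{path}: scenario {i} must be a mapping with a 'name'")
        block = dict(block)
        name = str(block.pop("name"))
        years = block.pop("years", None)
        if {"pi2", "pi3", "pi4"} & block.keys():
            block["pis"] = (block.pop("pi2"), block.pop("pi3"), block.pop("pi4"))
        try:
            scenarios.append(
                Scenario(
                    name=name,
                    overrides=block,
                    years=tuple(years) if years is not None else None,
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: scenario {name!r}: {exc}") from exc
    return scenarios


def read_cohort_config(path: str | Path):
    """Read a synthetic-cohort configuration (YAML mapping of
    :class:`pharmprev.synthetic.CohortConfig` fields)."""
    from .synthetic import CohortConfig

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: cohort config must be a key-value mapping")
    if "regimen_probs" in raw:
        raw["regimen_probs"] = tuple(raw["regimen_probs"])
    if "regions" in raw:
        raw["regions"] = tuple((str(r), float(s)) for r, s in raw["regions"])
    try:
        return CohortConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the package's CSV dialect (full precision,
    deterministic byte output for identical input)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")


def render_consumption(consumption: pd.DataFrame) -> pd.DataFrame:
    """Order a consumption table for reporting.

    Classes follow the canonical A10 report order (insulin subgroups, the
    insulin total, NAD subgroups, the NAD total), unknown classes last;
    a one-decimal ``did_report`` column is appended.
    """
    rank = {cls: i for i, cls in enumerate(A10_REPORT_ORDER)}
    out = consumption.copy()
    out["_rank"] = [rank.get(c, len(rank)) for c in out["atc_class"]]
    out = out.sort_values(
        ["year", "region", "_rank", "atc_class"], ignore_index=True
    ).drop(columns="_rank")
    out["did_report"] = [round_half_up(v) for v in out["did"]]
    return out


def render_estimates(estimates: pd.DataFrame) -> pd.DataFrame:
    """Order an estimates table for reporting: regions alphabetically,
    the TOTAL row last within each year."""
    out = estimates.copy()
    out["_rank"] = (out["scope"] == TOTAL_LABEL).astype(int)
    return out.sort_values(
        ["year", "_rank", "scope"], ignore_index=True
    ).drop(columns="_rank")


def render_scenarios(table: pd.DataFrame) -> pd.DataFrame:
    """Scenario table for reporting, base block first (run order kept)."""
    return table.reset_index(drop=True)
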