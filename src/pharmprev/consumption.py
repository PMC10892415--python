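"""DDD/DID consumption accounting from dispensing records.

Two quantities summarise drug utilisation:

* total DDD consumed = ``n_units x strength / DDD`` summed over sales
  (for unit-dose (UD) combination products, ``n_units / DDD``);
* DID = ``total DDD x 1000 / (inhabitants x 365)``, the number of Defined
  Daily Doses dispensed per 1000 inhabitants per day — roughly the
  per-mille of the population receiving the standard dose daily.

Records are aggregated per (region, year, ATC class prefix), with a TOTAL
row per (year, class) computed against the summed population — never as a
mean of regional DIDs.
"""

from __future__ import annotations

import logging

import pandas as pd

from .atc import DDDRegistry, MissingDDDError, atc_level, validate_atc

__all__ = [
    "DAYS_PER_YEAR",
    "TOTAL_LABEL",
    "RECORD_COLUMNS",
    "record_total_ddd",
    "did",
    "aggregate_consumption",
    "records_matching_did",
    "class_share",
    "did_change",
]

logger = logging.getLogger(__name__)

#: year length used throughout DID accounting, irrespective of calendar year
DAYS_PER_YEAR = 365

#: scope label of rows aggregated over all regions
TOTAL_LABEL = "TOTAL"

RECORD_COLUMNS = ["atc", "n_units", "strength", "region", "year"]
POPULATION_COLUMNS = ["region", "year", "inhabitants"]
CONSUMPTION_COLUMNS = ["region", "year", "atc_class", "total_ddd", "did"]


def record_total_ddd(record, registry: DDDRegistry) -> float:
    """DDD content of one dispensing record (a mapping with the record fields).

    ``n_units x strength / ddd_quantity``; for UD-denominated entries
    (fixed-dose combinations) strength is dimensionless and the unit count
    divides the DDD directly.
    """
    entry = registry.lookup(record["atc"])
    n_units = float(record["n_units"])
    if n_units < 0:
        raise ValueError(f"n_units must be non-negative, got {n_units}")
    if entry.ddd_unit == "UD":
        return n_units / entry.ddd_quantity
    strength = float(record["strength"])
    if not strength > 0:
        raise ValueError(f"strength must be positive, got {strength}")
    return n_units * strength / entry.ddd_quantity


def did(total_ddd: float, inhabitants: int, days: int = DAYS_PER_YEAR) -> float:
    """DDD per 1000 inhabitants per day."""
    if not inhabitants > 0:
        raise ValueError(f"inhabitants must be positive, got {inhabitants}")
    if total_ddd < 0:
        raise ValueError(f"total_ddd must be non-negative, got {total_ddd}")
    return total_ddd * 1000.0 / (inhabitants * days)


def _normalise_regions(series: pd.Series) -> pd.Series:
    # free-string labels matched exactly; the only normalisation is trimming
    return series.astype(str).str.strip()


def aggregate_consumption(
    records: pd.DataFrame,
    registry: DDDRegistry,
    population: pd.DataFrame,
    level: int = 4,
    *,
    permissive: bool = False,
    coverage_factor: float = 1.0,
) -> pd.DataFrame:
    """Aggregate dispensing records into a consumption table.

    Parameters
    ----------
    records
        Columns ``atc, n_units, strength, region, year``.
    registry
        DDD lookup; codes absent from it raise :class:`MissingDDDError`
        unless ``permissive`` is set, in which case the offending rows are
        skipped with a logged warning (skipped unit totals are recorded in
        ``result.attrs["skipped_units"]``).
    population
        Columns ``region, year, inhabitants``; every record's (region, year)
        must appear here.
    level
        ATC hierarchy level of the output class column (3 for the
        insulin/NAD split the prevalence model consumes, 4 for
        chemical-subgroup reporting).
    coverage_factor
        Multiplier applied to total DDD to scale a partial-market database
        up to full coverage; default 1 (no scaling).

    Returns
    -------
    DataFrame with columns ``region, year, atc_class, total_ddd, did``,
    including a ``TOTAL`` region row per (year, class).
    """
    if coverage_factor <= 0:
        raise ValueError(f"coverage_factor must be positive, got {coverage_factor}")
    records = records.copy()
    missing_cols = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records table missing columns: {missing_cols}")
    pop = population.copy()
    missing_cols = [c for c in POPULATION_COLUMNS if c not in pop.columns]
    if missing_cols:
        raise ValueError(f"population table missing columns: {missing_cols}")

    records["region"] = _normalise_regions(records["region"])
    pop["region"] = _normalise_regions(pop["region"])
    if pop.duplicated(["region", "year"]).any():
        dupes = pop[pop.duplicated(["region", "year"])]
        raise ValueError(f"duplicate population entries: {dupes.to_dict('records')}")
    if (pop["inhabitants"] <= 0).any():
        bad = pop[pop["inhabitants"] <= 0]
        raise ValueError(f"non-positive inhabitants in population rows: {bad.index.tolist()}")

    pop_index = pop.set_index(["region", "year"])["inhabitants"]
    rec_keys = set(zip(records["region"], records["year"]))
    absent = sorted(k for k in rec_keys if k not in pop_index.index)
    if absent:
        raise KeyError(f"record (region, year) pairs absent from population table: {absent}")

    ddds = []
    keep = []
    skipped_units: dict[str, float] = {}
    for idx, row in enumerate(records.itertuples(index=False)):
        rec = row._asdict()
        try:
            ddds.append(record_total_ddd(rec, registry))
            keep.append(idx)
        except MissingDDDError as exc:
            if not permissive:
                raise
            skipped_units[exc.code] = skipped_units.get(exc.code, 0.0) + float(rec["n_units"])
            logger.warning(
                "skipping record with unknown ATC code %s (%s units)",
                exc.code, rec["n_units"],
            )
    if skipped_units:
        logger.warning(
            "permissive mode skipped %d unit(s) across %d unknown code(s)",
            sum(skipped_units.values()), len(skipped_units),
        )

    kept = records.iloc[keep].copy()
    kept["total_ddd"] = [d * coverage_factor for d in ddds]
    kept["atc_class"] = [atc_level(c, level) for c in kept["atc"]]

    grouped = (
        kept.groupby(["region", "year", "atc_class"], as_index=False)["total_ddd"].sum()
    )

    # TOTAL row: sum DDD over regions, divide by the summed population of
    # *all* regions in the population table for that year (regions with no
    # sales still count in the denominator).
    totals = grouped.groupby(["year", "atc_class"], as_index=False)["total_ddd"].sum()
    totals.insert(0, "region", TOTAL_LABEL)
    pop_totals = pop.groupby("year")["inhabitants"].sum()

    def _inhabitants(region: str, year: int) -> int:
        if region == TOTAL_LABEL:
            return int(pop_totals.loc[year])
        return int(pop_index.loc[(region, year)])

    out = pd.concat([grouped, totals], ignore_index=True)
    out["did"] = [
        did(t, _inhabitants(r, y))
        for r, y, t in zip(out["region"], out["year"], out["total_ddd"])
    ]
    out = out[CONSUMPTION_COLUMNS].sort_values(
        ["year", "region", "atc_class"], ignore_index=True
    )
    out.attrs["skipped_units"] = skipped_units
    return out


def records_matching_did(
    atc: str,
    did_value: float,
    inhabitants: int,
    region: str,
    year: int,
    registry: DDDRegistry,
) -> pd.DataFrame:
    """Construct a single dispensing record whose aggregate DID equals
    ``did_value`` for the given population — the exact inverse of the DID
    formula.  Useful for rebuilding record-level inputs from published
    consumption tables.
    """
    code = validate_atc(atc)
    entry = registry.lookup(code)
    total_ddd = did_value * inhabitants * DAYS_PER_YEAR / 1000.0
    if entry.ddd_unit == "UD":
        n_units = total_ddd * entry.ddd_quantity
        strength = 1.0
    else:
        strength = entry.ddd_quantity
        n_units = total_ddd
    return pd.DataFrame(
        [{"atc": code, "n_units": n_units, "strength": strength,
          "region": region, "year": year}]
    )


def _select_did(consumption: pd.DataFrame, atc_class: str, year: int) -> pd.Series:
    cls = validate_atc(atc_class)
    rows = consumption[(consumption["atc_class"] == cls) & (consumption["year"] == year)]
    return rows["did"]


def class_share(
    consumption: pd.DataFrame,
    atc_class: str,
    year: int,
    *,
    total_class: str = "A10",
) -> float:
    """Share (%) of one class's DID in an ancestor class total.

    Published consumption tables round each row independently, so an
    ancestor's own printed total can differ (in the last decimal) from the
    sum of its subclasses; when the table carries a row for
    ``total_class`` that row is the denominator, otherwise the matching
    subclass DIDs are summed.  Single-scope tables only (filter a
    multi-region table first).
    """
    num = _select_did(consumption, atc_class, year)
    if len(num) != 1:
        raise ValueError(
            f"expected exactly one {atc_class!r} cell for {year}, found {len(num)}"
        )
    denom_rows = _select_did(consumption, total_class, year)
    if len(denom_rows) == 1:
        denom = float(denom_rows.iloc[0])
    elif len(denom_rows) == 0:
        prefix = validate_atc(total_class)
        mask = (
            consumption["atc_class"].str.startswith(prefix)
            & (consumption["year"] == year)
        )
        denom = float(consumption.loc[mask, "did"].sum())
    else:
        raise ValueError(f"multiple {total_class!r} cells for {year}")
    if denom <= 0:
        raise ValueError(f"non-positive total DID for {total_class!r} in {year}")
    return 100.0 * float(num.iloc[0]) / denom


def did_change(
    consumption: pd.DataFrame, atc_class: str, year_from: int, year_to: int
) -> float:
    """Relative DID change (%) of a class between two years."""
    start = _select_did(consumption, atc_class, year_from)
    end = _select_did(consumption, atc_class, year_to)
    if len(start) != 1 or len(end) != 1:
        raise ValueError(
            f"expected exactly one {atc_class!r} cell per year, found "
            f"{len(start)} ({year_from}) and {len(end)} ({year_to})"
        )
    if float(start.iloc[0]) <= 0:
        raise ValueError(f"cannot compute change from non-positive DID in {year_from}")
    return 100.0 * (float(end.iloc[0]) - float(start.iloc[0])) / float(start.iloc[0])
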