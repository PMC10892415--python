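"""Synthetic person-level cohorts and the dispensing records they generate.

The generator produces a population whose statistical structure matches
every assumption the prevalence estimator makes, so that running the full
pipeline on simulated sales must recover the cohort's known prevalence.
Each person carries one of five statuses:

``healthy``
    no antidiabetic exposure;
``t2dm_undiagnosed``
    T2DM without diagnosis, hence untreated and invisible to sales data;
``t2dm_nad``
    diagnosed T2DM on one to four non-insulin drug classes (regimen size
    distributed per the concomitance probabilities ``pi1..pi4``);
``t2dm_insulin``
    diagnosed T2DM treated with insulin only;
``t1dm``
    Type 1 diabetes, insulin only — present so the estimator's
    insulin-user exclusion is exercised non-trivially.

Within the T2DM group, a fraction ``u`` is undiagnosed; of the treated
remainder, a fraction ``f`` uses insulin and the rest use NADs.  In
``deterministic`` mode all counts are exact expected values (largest-
remainder apportionment) and every treated person contributes exactly
``adherence x 365`` DDD per drug; in ``stochastic`` mode statuses and
regimens are drawn multinomially and each person-drug's 365 treatment days
are thinned binomially with the adherence probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atc import DDDRegistry, atc_level
from .consumption import DAYS_PER_YEAR, TOTAL_LABEL
from .model import ModelParams

__all__ = [
    "CohortConfig",
    "STATUSES",
    "largest_remainder",
    "generate_cohort",
    "simulate_dispensing",
    "true_summary",
    "population_table",
    "matched_model_params",
]

STATUSES = ["healthy", "t2dm_undiagnosed", "t2dm_nad", "t2dm_insulin", "t1dm"]


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a simulated population.

    Defaults mirror the base-case study conditions of the estimator: an
    overall T2DM prevalence of 13.9%, 44% of cases undiagnosed, 7.5% of
    treated cases on insulin, 60% NAD adherence with full insulin
    adherence, and regimen-size probabilities implying a concomitance
    weight of ~0.608.  T1DM prevalence defaults to 0.5% so the insulin-only
    exclusion has something to exclude.
    """

    n_pop: int = 100_000
    true_prevalence: float = 0.139
    undiagnosed_fraction: float = 0.44
    insulin_t2dm_fraction: float = 0.075
    t1dm_prevalence: float = 0.005
    regimen_probs: tuple[float, float, float, float] = (0.545, 0.30, 0.12, 0.035)
    adherence_nad: float = 0.60
    adherence_insulin: float = 1.00
    regions: tuple[tuple[str, float], ...] = (("PT", 1.0),)
    mode: str = "deterministic"
    seed: int = 0
    year: int = 2018
    pack_size: int | None = None

    def __post_init__(self) -> None:
        if self.n_pop <= 0:
            raise ValueError(f"n_pop must be positive, got {self.n_pop}")
        if not 0 <= self.true_prevalence <= 1:
            raise ValueError(f"true_prevalence must be in [0, 1], got {self.true_prevalence}")
        if not 0 <= self.undiagnosed_fraction < 1:
            raise ValueError(
                f"undiagnosed_fraction must be in [0, 1), got {self.undiagnosed_fraction}"
            )
        if not 0 <= self.insulin_t2dm_fraction <= 1:
            raise ValueError(
                f"insulin_t2dm_fraction must be in [0, 1], got {self.insulin_t2dm_fraction}"
            )
        if not 0 <= self.t1dm_prevalence <= 1:
            raise ValueError(f"t1dm_prevalence must be in [0, 1], got {self.t1dm_prevalence}")
        if self.true_prevalence + self.t1dm_prevalence > 1:
            raise ValueError("prevalences sum above 1: population infeasible")
        if len(self.regimen_probs) != 4 or any(p < 0 for p in self.regimen_probs):
            raise ValueError(f"regimen_probs must be 4 non-negative values, got {self.regimen_probs}")
        if abs(sum(self.regimen_probs) - 1.0) > 1e-9:
            raise ValueError(f"regimen_probs must sum to 1, got {self.regimen_probs}")
        for name in ("adherence_nad", "adherence_insulin"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        shares = [s for _, s in self.regions]
        if any(s < 0 for s in shares) or abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError(f"region shares must be non-negative and sum to 1, got {shares}")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"mode must be 'deterministic' or 'stochastic', got {self.mode!r}")
        if self.pack_size is not None and self.pack_size <= 0:
            raise ValueError(f"pack_size must be positive, got {self.pack_size}")

    def status_probs(self) -> np.ndarray:
        """Joint probabilities of the five statuses, in ``STATUSES`` order."""
        p, u, f = self.true_prevalence, self.undiagnosed_fraction, self.insulin_t2dm_fraction
        treated = p * (1.0 - u)
        probs = np.array([
            1.0 - p - self.t1dm_prevalence,     # healthy
            p * u,                              # t2dm_undiagnosed
            treated * (1.0 - f),                # t2dm_nad
            treated * f,                        # t2dm_insulin
            self.t1dm_prevalence,               # t1dm
        ])
        return probs


def largest_remainder(total: int, probs: Sequence[float]) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``probs``.

    Hamilton's method: floor the exact quotas, then distribute the leftover
    units to the largest fractional remainders (ties broken by position,
    earlier first), so the counts always sum to ``total`` and each count
    differs from its exact quota by less than 1.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.sum() <= 0:
        raise ValueError("probabilities must have a positive sum")
    quotas = total * probs / probs.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder:
        order = np.lexsort((np.arange(len(probs)), -(quotas - counts)))
        counts[order[:remainder]] += 1
    return counts


def _nad_formulary(registry: DDDRegistry) -> dict[str, list[str]]:
    """Level-4 chemical subgroups -> level-5 codes, NAD classes only."""
    classes: dict[str, list[str]] = {}
    for code in registry.codes("A10B"):
        classes.setdefault(atc_level(code, 4), []).append(code)
    if not classes:
        raise ValueError("registry holds no A10B (NAD) codes")
    return classes


def generate_cohort(config: CohortConfig, registry: DDDRegistry) -> pd.DataFrame:
    """Generate one person per row: ``status``, ``regimen``, ``region``.

    ``regimen`` is a tuple of level-5 ATC codes: 1-4 NAD codes from distinct
    chemical subgroups for ``t2dm_nad`` persons, exactly one insulin code
    for ``t2dm_insulin`` and ``t1dm`` persons, empty otherwise.  The same
    seed always yields the same cohort.
    """
    rng = np.random.default_rng(config.seed)
    probs = config.status_probs()
    if config.mode == "deterministic":
        status_counts = largest_remainder(config.n_pop, probs)
    else:
        status_counts = rng.multinomial(config.n_pop, probs)

    nad_classes = _nad_formulary(registry)
    class_names = sorted(nad_classes)
    if len(class_names) < 4 and any(config.regimen_probs[k] > 0 for k in range(len(class_names), 4)):
        raise ValueError(
            f"regimen sizes up to {max(k + 1 for k in range(4) if config.regimen_probs[k] > 0)} "
            f"requested but the registry holds only {len(class_names)} NAD classes"
        )
    insulin_codes = registry.codes("A10A")
    needs_insulin = status_counts[STATUSES.index("t2dm_insulin")] + status_counts[
        STATUSES.index("t1dm")
    ]
    if needs_insulin and not insulin_codes:
        raise ValueError("registry holds no A10A (insulin) codes")

    statuses: list[str] = []
    regimens: list[tuple[str, ...]] = []
    for status, count in zip(STATUSES, status_counts):
        statuses.extend([status] * int(count))
        if status == "t2dm_nad":
            if config.mode == "deterministic":
                size_counts = largest_remainder(int(count), config.regimen_probs)
            else:
                size_counts = rng.multinomial(int(count), config.regimen_probs)
            for size, n_size in zip((1, 2, 3, 4), size_counts):
                n_size = int(n_size)
                if n_size == 0:
                    continue
                # uniform draws of `size` distinct classes: argsort of random
                # keys is a uniform permutation, take its head
                keys = rng.random((n_size, len(class_names)))
                class_idx = np.argsort(keys, axis=1)[:, :size]
                drug_keys = rng.integers(0, 2**31, size=(n_size, size))
                for row_classes, row_keys in zip(class_idx, drug_keys):
                    regimens.append(
                        tuple(
                            nad_classes[class_names[c]][k % len(nad_classes[class_names[c]])]
                            for c, k in zip(row_classes, row_keys)
                        )
                    )
        elif status in ("t2dm_insulin", "t1dm"):
            picks = rng.integers(len(insulin_codes), size=int(count))
            regimens.extend((insulin_codes[p],) for p in picks)
        else:
            regimens.extend([()] * int(count))

    shares = [s for _, s in config.regions]
    labels = [r for r, _ in config.regions]
    regions: list[str] = []
    # region assignment is apportioned within each status block so that
    # regional prevalences match the configured shares in deterministic mode
    for count in status_counts:
        block = int(count)
        if config.mode == "deterministic":
            region_counts = largest_remainder(block, shares)
            for label, n_region in zip(labels, region_counts):
                regions.extend([label] * int(n_region))
        else:
            regions.extend(rng.choice(labels, size=block, p=shares))

    return pd.DataFrame({"status": statuses, "regimen": regimens, "region": regions})


def simulate_dispensing(
    persons: pd.DataFrame, registry: DDDRegistry, config: CohortConfig
) -> pd.DataFrame:
    """Turn a cohort into aggregated dispensing records.

    Every treated person-drug pair represents 365 potential treatment days;
    a day's DDD is dispensed with probability equal to the adherence for
    the drug's class (exactly ``adherence x 365`` DDD in deterministic
    mode, binomially thinned in stochastic mode).  DDD totals are converted
    to dose units at a fixed strength per product (half a DDD per unit for
    oral mg products, 300 IU pens for insulins, unit doses for fixed-dose
    combinations) and summed per (ATC code, region).

    With ``config.pack_size`` set, each person-drug's annual unit count is
    rounded up to whole packs of that many units before aggregation,
    emulating pack-level sales quantisation.
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of cohort draw
    pairs = persons[persons["regimen"].map(len) > 0]
    if pairs.empty:
        return pd.DataFrame(columns=["atc", "n_units", "strength", "region", "year"])
    exploded = pairs.explode("regimen")[["status", "regimen", "region"]]
    exploded = exploded.rename(columns={"regimen": "atc"})
    adherence = np.where(
        exploded["status"].isin(["t2dm_insulin", "t1dm"]),
        config.adherence_insulin,
        config.adherence_nad,
    )
    if config.mode == "deterministic":
        ddd = adherence * DAYS_PER_YEAR
    else:
        ddd = rng.binomial(DAYS_PER_YEAR, adherence).astype(float)

    entries = {code: registry.lookup(code) for code in exploded["atc"].unique()}
    strength = np.empty(len(exploded))
    units_per_ddd = np.empty(len(exploded))
    for i, code in enumerate(exploded["atc"]):
        entry = entries[code]
        if entry.ddd_unit == "UD":
            strength[i] = 1.0
            units_per_ddd[i] = entry.ddd_quantity
        elif entry.ddd_unit == "IU":
            strength[i] = 300.0  # one pen/cartridge of 300 IU
            units_per_ddd[i] = entry.ddd_quantity / 300.0
        else:
            strength[i] = entry.ddd_quantity / 2.0  # two dose units per DDD
            units_per_ddd[i] = 2.0
    n_units = ddd * units_per_ddd
    if config.pack_size is not None:
        n_units = np.ceil(n_units / config.pack_size) * config.pack_size

    frame = pd.DataFrame(
        {
            "atc": exploded["atc"].to_numpy(),
            "n_units": n_units,
            "strength": strength,
            "region": exploded["region"].to_numpy(),
        }
    )
    records = (
        frame.groupby(["atc", "strength", "region"], as_index=False)["n_units"].sum()
    )
    records["year"] = config.year
    return records[["atc", "n_units", "strength", "region", "year"]].sort_values(
        ["region", "atc"], ignore_index=True
    )


def true_summary(persons: pd.DataFrame) -> pd.DataFrame:
    """Exact prevalence ground truth by region plus a TOTAL row.

    Treated T2DM prevalence counts ``t2dm_nad`` and ``t2dm_insulin``;
    overall prevalence adds the undiagnosed.  T1DM never counts.
    """
    def _summarise(group: pd.DataFrame) -> dict:
        n = len(group)
        counts = group["status"].value_counts()
        treated = int(counts.get("t2dm_nad", 0) + counts.get("t2dm_insulin", 0))
        overall = treated + int(counts.get("t2dm_undiagnosed", 0))
        return {
            "n": n,
            "n_t2dm_nad": int(counts.get("t2dm_nad", 0)),
            "n_t2dm_insulin": int(counts.get("t2dm_insulin", 0)),
            "n_t2dm_undiagnosed": int(counts.get("t2dm_undiagnosed", 0)),
            "n_t1dm": int(counts.get("t1dm", 0)),
            "treated_prev_pct": 100.0 * treated / n if n else 0.0,
            "overall_prev_pct": 100.0 * overall / n if n else 0.0,
        }

    rows = []
    for region, group in persons.groupby("region"):
        rows.append({"region": region, **_summarise(group)})
    rows.append({"region": TOTAL_LABEL, **_summarise(persons)})
    return pd.DataFrame(rows)


def population_table(config: CohortConfig, persons: pd.DataFrame | None = None) -> pd.DataFrame:
    """Region/year/inhabitants table for the simulated population.

    With ``persons`` given, counts the realised cohort (the correct
    denominator in stochastic mode, where region draws fluctuate around
    the configured shares); otherwise apportions ``n_pop`` by the shares.
    """
    if persons is not None:
        counts = persons["region"].value_counts()
        rows = [
            {"region": region, "year": config.year, "inhabitants": int(n)}
            for region, n in counts.items()
        ]
    else:
        shares = [s for _, s in config.regions]
        counts = largest_remainder(config.n_pop, shares)
        rows = [
            {"region": label, "year": config.year, "inhabitants": int(n)}
            for (label, _), n in zip(config.regions, counts)
        ]
    return pd.DataFrame(rows, columns=["region", "year", "inhabitants"]).sort_values(
        "region", ignore_index=True
    )


def matched_model_params(config: CohortConfig, persons: pd.DataFrame | None = None) -> ModelParams:
    """Model parameters under which the estimator matches the generator.

    The concomitance weight and the insulin-user fraction are the two
    places where the estimator's operational parameters differ from the
    generative fractions:

    * ``w`` must equal ``n_nad_persons / n_class_patient_equivalents``;
      computed from the realised regimen sizes when ``persons`` is given
      (exact, since apportionment perturbs the configured probabilities),
      else from the configured ``pi``'s.
    * the estimator applies its insulin fraction to *all* insulin users
      (T1DM included), so the matching value is
      ``n_t2dm_insulin / (n_t2dm_insulin + n_t1dm)``, not the generative
      fraction-of-treated ``f``.
    """
    if persons is not None:
        sizes = persons.loc[persons["status"] == "t2dm_nad", "regimen"].map(len)
        n_nad = len(sizes)
        equivalents = int(sizes.sum())
        w = n_nad / equivalents if equivalents else 1.0
        n_ins_t2 = int((persons["status"] == "t2dm_insulin").sum())
        n_ins_t1 = int((persons["status"] == "t1dm").sum())
        pool = n_ins_t2 + n_ins_t1
        f = n_ins_t2 / pool if pool else 0.0
    else:
        pi1, pi2, pi3, pi4 = config.regimen_probs
        w = 1.0 / (1.0 + pi2 + 2.0 * pi3 + 3.0 * pi4)
        p, u = config.true_prevalence, config.undiagnosed_fraction
        ins_t2 = p * (1.0 - u) * config.insulin_t2dm_fraction
        pool = ins_t2 + config.t1dm_prevalence
        f = ins_t2 / pool if pool else 0.0
    return ModelParams(
        adherence_nad=config.adherence_nad,
        adherence_insulin=config.adherence_insulin,
        w=w,
        insulin_t2dm_fraction=f,
        undiagnosed_fraction=config.undiagnosed_fraction,
    )
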