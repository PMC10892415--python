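"""Six-step indirect prevalence estimator for treated and overall T2DM.

The estimator converts population-level antidiabetic consumption (DID) into
a prevalence estimate by sequential adjustment, in the spirit of the
Sartor–Walckiers consumption-to-prevalence frame
``p = sum_i v_i c_i / N`` realised as a step chain:

1. **Patient-day equivalents.**  ``DID x N / 1000`` persons would account
   for the observed consumption if each took exactly one DDD per day.
2. **Adherence.**  Observed dispensing under-counts patients when adherence
   is partial: divide by the adherence fraction (0.60 for NADs, 1.00 for
   insulins in the base case).
3. **Concomitance.**  Patients on k NAD classes are counted k times by
   step 1; multiply by the weight factor ``w = 1/(1 + pi2 + 2 pi3 + 3 pi4)``
   where ``pi_k`` is the probability of a k-drug regimen (base w = 0.608).
4. **Insulin-user split.**  Insulin consumption counts a mix of T1DM and
   T2DM users.  All insulin-derived patients are excluded, then the
   fraction ``f`` (base 0.075) is re-admitted as T2DM insulin users:
   ``patients_T2DM = NAD_adjusted + f x insulin_patients``.
5. **Treated prevalence.**  ``100 x patients_T2DM / N``.
6. **Undiagnosed correction.**  Overall prevalence =
   treated / (1 - u), with u the undiagnosed fraction (0.44 for 2018,
   0.357 for 2021 in the base case).

Patient counts stay as reals throughout; percentages are rounded half-up
to one decimal only in the ``*_report`` columns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

from .atc import classify_ad
from .consumption import TOTAL_LABEL

__all__ = [
    "ModelParams",
    "round_half_up",
    "patients_from_did",
    "adjust_adherence",
    "weight_factor",
    "apply_concomitance",
    "t2dm_treated",
    "patients_dm_total",
    "prevalence_treated",
    "prevalence_overall",
    "run_model",
]

ESTIMATE_COLUMNS = [
    "scope", "year", "patients_dm", "patients_t2dm",
    "prev_treated_pct", "prev_overall_pct",
    "prev_treated_report", "prev_overall_report",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (2.25 -> 2.3 at one digit), the convention used
    for all reported percentages."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ModelParams:
    """The five adjustable parameters of the estimator.

    Exactly one of ``w`` (the concomitance weight factor) or ``pis``
    (the regimen-size probabilities ``(pi2, pi3, pi4)`` from which w is
    derived) may be supplied; with neither, the base-case w = 0.608 applies.
    """

    adherence_nad: float = 0.60
    adherence_insulin: float = 1.00
    w: float | None = None
    pis: tuple[float, float, float] | None = None
    insulin_t2dm_fraction: float = 0.075
    undiagnosed_fraction: float = 0.44

    def __post_init__(self) -> None:
        if self.w is not None and self.pis is not None:
            raise ValueError("supply either w or pis, not both")
        if self.w is None and self.pis is None:
            object.__setattr__(self, "w", 0.608)
        for name in ("adherence_nad", "adherence_insulin"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.w is not None and not 0 < self.w <= 1:
            raise ValueError(f"w must be in (0, 1], got {self.w}")
        if not 0 <= self.insulin_t2dm_fraction <= 1:
            raise ValueError(
                f"insulin_t2dm_fraction must be in [0, 1], got {self.insulin_t2dm_fraction}"
            )
        if not 0 <= self.undiagnosed_fraction < 1:
            raise ValueError(
                f"undiagnosed_fraction must be in [0, 1), got {self.undiagnosed_fraction}"
            )

    @property
    def effective_w(self) -> float:
        """The concomitance weight, derived from ``pis`` when supplied."""
        if self.w is not None:
            return self.w
        return weight_factor(*self.pis)

    def replace(self, **overrides) -> "ModelParams":
        """Copy with fields overridden; setting ``w`` clears ``pis`` and
        vice versa, so one-at-a-time scenario overrides stay well-formed."""
        if "w" in overrides and "pis" not in overrides:
            overrides.setdefault("pis", None)
        if "pis" in overrides and overrides["pis"] is not None and "w" not in overrides:
            overrides.setdefault("w", None)
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown ModelParams field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)


def patients_from_did(did: float, inhabitants: int) -> float:
    """Step 1: persons consuming exactly one DDD/day behind a DID level."""
    if not inhabitants > 0:
        raise ValueError(f"inhabitants must be positive, got {inhabitants}")
    if did < 0:
        raise ValueError(f"did must be non-negative, got {did}")
    return did * inhabitants / 1000.0


def adjust_adherence(patients: float, adherence: float) -> float:
    """Step 2: inflate the patient count by imperfect adherence."""
    if not 0 < adherence <= 1:
        raise ValueError(f"adherence must be in (0, 1], got {adherence}")
    return patients / adherence


def weight_factor(pi2: float, pi3: float, pi4: float) -> float:
    """Concomitance weight ``w = 1/(1 + pi2 + 2 pi3 + 3 pi4)``.

    ``pi_k`` is the probability that a treated patient takes k NAD classes
    simultaneously; w converts class-patient-equivalents into persons.
    """
    pis = (pi2, pi3, pi4)
    if any(p < 0 for p in pis):
        raise ValueError(f"regimen probabilities must be non-negative, got {pis}")
    if pi2 + pi3 + pi4 > 1 + 1e-12:
        raise ValueError(f"regimen probabilities sum above 1: {pis}")
    return 1.0 / (1.0 + pi2 + 2.0 * pi3 + 3.0 * pi4)


def apply_concomitance(patients: float, w: float) -> float:
    """Step 3: collapse multi-drug counting with the weight factor."""
    if not 0 < w <= 1:
        raise ValueError(f"w must be in (0, 1], got {w}")
    return patients * w


def t2dm_treated(nad_patients_adj: float, insulin_patients: float, f: float) -> float:
    """Step 4: NAD-treated patients plus the T2DM share of insulin users."""
    if not 0 <= f <= 1:
        raise ValueError(f"insulin fraction must be in [0, 1], got {f}")
    if nad_patients_adj < 0 or insulin_patients < 0:
        raise ValueError("patient counts must be non-negative")
    return nad_patients_adj + f * insulin_patients


def patients_dm_total(nad_patients_adj: float, insulin_patients: float) -> float:
    """All patients in pharmacological treatment for diabetes (any type)."""
    if nad_patients_adj < 0 or insulin_patients < 0:
        raise ValueError("patient counts must be non-negative")
    return nad_patients_adj + insulin_patients


def prevalence_treated(patients_t2dm: float, inhabitants: int) -> float:
    """Step 5: treated prevalence as a percentage of the population."""
    if not inhabitants > 0:
        raise ValueError(f"inhabitants must be positive, got {inhabitants}")
    return 100.0 * patients_t2dm / inhabitants


def prevalence_overall(prev_treated_pct: float, u: float) -> float:
    """Step 6: inflate treated prevalence by the undiagnosed fraction."""
    if not 0 <= u < 1:
        raise ValueError(f"undiagnosed fraction must be in [0, 1), got {u}")
    return prev_treated_pct / (1.0 - u)


def _params_for_year(
    params: "ModelParams | Mapping[int, ModelParams]", year: int
) -> ModelParams:
    if isinstance(params, ModelParams):
        return params
    try:
        return params[year]
    except KeyError:
        raise KeyError(f"no model parameters supplied for year {year}") from None


def run_model(
    consumption: pd.DataFrame,
    population: pd.DataFrame,
    params: "ModelParams | Mapping[int, ModelParams]",
    *,
    scopes: list[str] | None = None,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Run the full step chain on a consumption table.

    ``consumption`` is the output of
    :func:`pharmprev.consumption.aggregate_consumption` at any ATC level:
    cells are classified into insulin (A10A) / NAD (A10B) and their DIDs
    summed per scope and year (DID is additive over a class partition).
    ``params`` may be a single :class:`ModelParams` or a mapping
    ``year -> ModelParams`` when e.g. the undiagnosed fraction differs by
    year.

    Returns one row per scope and year with full-precision patient counts
    and prevalences plus one-decimal report columns.
    """
    pop = population.copy()
    pop["region"] = pop["region"].astype(str).str.strip()
    pop_index = pop.set_index(["region", "year"])["inhabitants"]
    pop_totals = pop.groupby("year")["inhabitants"].sum()

    cells = consumption.copy()
    cells["ad_class"] = [classify_ad(c) for c in cells["atc_class"]]
    cells = cells[cells["ad_class"].isin(["insulin", "nad"])]
    dids = (
        cells.groupby(["region", "year", "ad_class"])["did"].sum().unstack(fill_value=0.0)
    )
    for col in ("insulin", "nad"):
        if col not in dids.columns:
            dids[col] = 0.0

    available = list(dids.index)
    if scopes is not None or years is not None:
        wanted = [
            (s, y)
            for s, y in available
            if (scopes is None or s in scopes) and (years is None or y in years)
        ]
        for s in scopes or []:
            if all(s != a for a, _ in wanted):
                raise KeyError(f"no consumption cells for scope {s!r}")
        for y in years or []:
            if all(y != b for _, b in wanted):
                raise KeyError(f"no consumption cells for year {y}")
    else:
        wanted = available

    rows = []
    for scope, year in wanted:
        p = _params_for_year(params, year)
        if scope == TOTAL_LABEL:
            inhabitants = int(pop_totals.loc[year])
        else:
            try:
                inhabitants = int(pop_index.loc[(scope, year)])
            except KeyError:
                raise KeyError(
                    f"population table has no entry for ({scope!r}, {year})"
                ) from None

        nad_raw = patients_from_did(dids.loc[(scope, year), "nad"], inhabitants)
        ins_raw = patients_from_did(dids.loc[(scope, year), "insulin"], inhabitants)
        nad_adh = adjust_adherence(nad_raw, p.adherence_nad)
        ins_adh = adjust_adherence(ins_raw, p.adherence_insulin)
        nad_adj = apply_concomitance(nad_adh, p.effective_w)
        t2dm = t2dm_treated(nad_adj, ins_adh, p.insulin_t2dm_fraction)
        dm = patients_dm_total(nad_adj, ins_adh)
        treated = prevalence_treated(t2dm, inhabitants)
        overall = prevalence_overall(treated, p.undiagnosed_fraction)
        rows.append(
            {
                "scope": scope,
                "year": year,
                "patients_dm": dm,
                "patients_t2dm": t2dm,
                "prev_treated_pct": treated,
                "prev_overall_pct": overall,
                "prev_treated_report": round_half_up(treated),
                "prev_overall_report": round_half_up(overall),
            }
        )
    out = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    return out.sort_values(["year", "scope"], ignore_index=True)
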