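# Methods

## The estimation problem

Dispensing databases record sales, not diagnoses. For a chronic disease
whose treatment is (i) mainly pharmacological, (ii) drug-specific, and
(iii) non-seasonal, aggregate consumption carries a prevalence signal:
each Defined Daily Dose (DDD) dispensed is, to first order, one
patient-day of standard treatment. `pharmprev` operationalises this for
T2DM, where antidiabetic drugs split cleanly into insulins (ATC A10A) and
non-insulin antidiabetics (NADs, A10B).

The consumption unit is DID — DDD per 1000 inhabitants per day:

```
total_DDD = Σ sales  n_units × strength / DDD        (UD entries: n_units / DDD)
DID       = total_DDD × 1000 / (N × 365)
```

The year length is fixed at 365 days regardless of calendar year, and DID
is kept at full precision internally; one-decimal rounding (half-up)
happens only in report columns. "Units" are dose units (tablets, pens),
never packages — packages carry no dosage dimension. Fixed-dose
combinations (A10BD) have their DDD expressed in unit doses (UD), so
their unit counts divide the DDD directly with no strength factor.

## The six-step model

Per scope (region or national total) and year, with N inhabitants:

| step | operation | parameter (base) |
|---|---|---|
| 1 | patient-day equivalents `DID × N / 1000`, per class | — |
| 2 | divide by adherence | NAD 0.60, insulin 1.00 |
| 3 | multiply NAD side by `w = 1/(1+π₂+2π₃+3π₄)` | w = 0.608 |
| 4 | `patients_T2DM = NAD_adj + f × insulin_patients` | f = 0.075 |
| 5 | `treated % = 100 × patients_T2DM / N` | — |
| 6 | `overall % = treated / (1 − u)` | u = 0.44 (2018), 0.357 (2021) |

Step 2 inflates counts because partial adherence means observed
consumption under-counts the treated population. Step 3 collapses the
multiple counting of patients on two to four concomitant NAD classes;
`π_k` is the probability of a k-class regimen. Step 4 deserves comment:
insulin consumption mixes T1DM and T2DM users, so all insulin-derived
patients are first excluded and the fraction *f* is then re-admitted as
T2DM insulin users. Operationally *f* multiplies the *insulin-user pool*;
the base value 0.075 is a published estimate of the European share of
T2DM patients using insulin, adopted for that role. These two readings
coincide only when the insulin pool is dominated by patients also counted
in the treated-T2DM denominator; the synthetic-recovery machinery makes
the distinction explicit (below).

Adjacent steps are multiplicative, hence commute; prevalence is strictly
decreasing in adherence and increasing in w, f and (overall only) u; and
the whole chain is invariant to jointly scaling population and sales.
The aggregate frame `p̂ = Σᵢ vᵢcᵢ / N` is realised by this chain rather
than implemented as a separate formula.

Patient counts remain reals throughout — rounding them to integers inside
the chain would be spurious precision, and reported percentages are
rounded half-up to one decimal only at the reporting boundary.

## Aggregation and reporting conventions

* Model input is the level-3 split {A10A, A10B}; consumption reports
  default to level 4 (chemical subgroups). DID is additive over a class
  partition, so any input level deeper than 3 is summed consistently.
* TOTAL rows divide summed DDD by the summed population — never the mean
  of regional DIDs.
* Published consumption tables round every row independently, so a
  printed class total can differ in the last decimal from the sum of its
  printed subclasses. Share computations therefore prefer the table's own
  total row as denominator when one is present (`class_share`).
* Region labels are free strings matched exactly after whitespace
  trimming. Missing DDD entries are a hard error; a permissive flag
  downgrades them to logged skips with per-code skipped-unit totals.
* An optional multiplicative coverage factor (default 1) scales a
  partial-market database toward full coverage; none is applied by
  default.

## Synthetic cohorts

`CohortConfig` defaults define the reference simulation conditions:
population 100 000 (200 000 in the recovery study), true T2DM prevalence
13.9%, undiagnosed fraction 0.44, insulin fraction of treated cases
0.075, NAD adherence 0.60, insulin adherence 1.00, T1DM prevalence 0.5%
(so the insulin-only exclusion is non-trivially exercised), and
regimen-size probabilities (π₁..π₄) = (0.545, 0.30, 0.12, 0.035), chosen
to imply w ≈ 0.608, the base-case concomitance weight.

Within the T2DM cases the split is nested: a fraction u is undiagnosed;
of the treated remainder, f uses insulin (insulin-only, no concurrent
NADs) and 1 − f uses NADs. Insulin-only generation is what makes the
NAD side and the insulin side of step 4 count disjoint persons; the
real-world insulin+NAD overlap violates that additivity and is a known
limitation, not a modelled feature. NAD regimens draw their 1–4 drugs
from distinct chemical subgroups (never two drugs of the same level-4
class), uniformly over the formulary.

Deterministic mode apportions all counts to exact expected values by
largest remainder and emits exactly `adherence × 365` DDD per
person-drug. Stochastic mode draws statuses and regimen sizes
multinomially and thins each person-drug's 365 treatment days binomially
with the adherence probability — mean-matched to the model's accounting,
with no overdispersion. An optional pack size rounds each person-drug's
annual units up to whole packs to probe quantisation bias (off by
default). Unit strengths are fixed per product class (half a DDD per
oral dose unit, 300 IU insulin pens, unit doses for combinations);
they cancel out of all DDD accounting.

`matched_model_params` converts a generating configuration into the
estimator parameters under which recovery is exact: w from the realised
regimen-size counts (apportionment perturbs the configured π's by less
than one person per cell) and the insulin fraction as
`n_T2DM_insulin / (n_T2DM_insulin + n_T1DM)` — the pool-share reading of
step 4. With those parameters, deterministic-mode recovery of treated and
overall prevalence is exact to floating precision, and the 20-seed
stochastic study at n = 200 000 shows mean absolute error ≈ 0.002
prevalence points with no detectable bias. What passing these checks
shows is internal consistency — the estimator inverts its own generative
assumptions; it cannot show that real dispensing data satisfy those
assumptions (uniform adherence, disjoint insulin/NAD users, no off-label
use, full market coverage).

## Sensitivity analysis

Scenarios are strictly one-at-a-time, mirroring how the parameter
uncertainty is reported in the drug-utilization literature: adherence
{0.50, 0.92}, insulin fraction {0.060, 0.158}, w = 0.596 (a re-derivation
from more recent multi-country prescription patterns), undiagnosed
fraction {0.098, 0.50}. The base block always leads the scenario table and
is bitwise identical to a direct model run. Scenarios varying u leave the
treated columns at base (u enters after step 5). `tornado_ranges` ranks
parameters by outcome spread — overall prevalence for u, treated
prevalence otherwise, with the base value always inside each range —
and reproduces the qualitative finding that adherence and the undiagnosed
fraction dominate w and f.

One published scenario pair is deliberately excluded from validation: the
two insulin-user rows of the published sensitivity table run opposite to
the monotonicity that the base-case-matching step-4 rule implies (a
larger f must raise, not lower, treated prevalence); the rows appear
transposed in the source and are reported by this package in the
direction the model's arithmetic dictates.

## Numerical and design choices

* Half-up decimal rounding for all reported percentages; validated
  against every reproducible published figure (7.8, 9.1, 13.9, 14.2, 9.3,
  10.9, 7.6, 9.0, 8.6, 10.1, 15.5, 18.3, 5.1, 6.0).
* Published patient *counts* were computed upstream from unrounded raw
  consumption; from the rounded published DIDs they are reproducible only
  to ≈0.1% and are checked at 0.2% relative tolerance.
* The packaged DDD registry is synthetic working data for the A10
  formulary (declared in the file itself), not an extract of the official
  ATC/DDD index; analyses of real data must supply a registry built from
  the official index. Insulin strengths are expressed in DDD-compatible
  IU throughout, sidestepping IU/ml labelling arbitration.
* `ModelParams` accepts either w directly or the π-decomposition, never
  both; scenario overrides switch representation safely.
* Degenerate inputs: zero consumption yields an all-zero estimate; an
  empty cohort yields zero prevalences; u = 0 makes overall equal
  treated; π = (1,0,0,0) makes w = 1 (no concomitance correction).

## Problem sizes

Unit and acceptance tests run the national desk-scale computation
(instantaneous) plus recovery studies at n = 100 000 (deterministic,
exact) and 20 × 200 000 (stochastic); the full suite completes in well
under a minute on a single core.

## Limitations

The estimator sees only diagnosed-and-treated disease; everything else
enters through the assumed u. DID cannot be stratified by sex or age.
Parameters (adherence, w, f, u) are literature values, not co-estimated
from the data, and the concomitance weight ages as prescription patterns
evolve. Off-label use of NADs (and, post-2021, the expanded indications
of GLP-1 and SGLT2 agents) inflates apparent prevalence and is not
modelled. Patients on both insulin and NADs break the step-4 additivity;
quantifying that bias is possible with the synthetic machinery but not
built in as a default condition.
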