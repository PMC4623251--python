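# Methods

## Model structure and assumptions

The model is a closed, one-year, prevalence-based decision tree. The
high-risk cohort is fixed at the start of the year (`total diabetes
population × high-risk fraction`); there is no recurrence, re-entry,
age structure, or discounting of health outcomes within the year. Health
care utilization is assumed complete and uniform: every ulcerated patient
receives care, and every high-risk person receives the prevention package
regardless of their eventual endpoint. Every in-hospital death is assumed
to follow an amputation in the same year, so deaths are split into
major-/minor-amputation subgroups with the same shares (f₁/f₂) as
surviving amputees. "Major amputations" as an outcome counts both healed
and deceased major amputees.

Person counts are carried as fractional persons at full floating-point
precision through every computation; rounding (half-up, away from zero) is
purely presentational and happens only in the report layer. The published
tables are reproducible only under this convention — the headline death
and amputation figures do not survive intermediate rounding.

## Parameters

All probabilities are decimals in `[0, 1]`; costs are 2012 US$ unless the
configuration says otherwise (the monthly minimum wage is entered in local
currency and converted once at the configured exchange rate).

| group | parameters | notes |
| --- | --- | --- |
| cohort | total diabetes population; high-risk fraction | product is the modelled cohort |
| ulceration | baseline prevalence `c`; effectiveness `e(s)` per strategy | `c` may be given as a back-calculation `p_ref / (1 − e_ref)`; an effectiveness may be given as a target prevalence |
| care setting | hospital share `d`; outpatient share `e = 1 − d` | validated complementary |
| hospital endpoints | amputation-and-heal `f`; debridement-and-heal `g`; death `h` | validated to sum to 1; `f₁`/`f₂` split amputations major/minor |
| costs | per-person prevention cost per strategy; per-episode unit costs for outpatient wound care, debridement, minor and major amputation | deceased patients incur the full cost of the amputation admission and nothing else |
| economics | monthly minimum wage (local), exchange rate, discount rate, retirement age, mean age at premature death, GDP per capita, threshold multiplier | |
| ranges | `(low, high)` per sensitivity parameter | must bracket the point estimate |

The bundled `peru_2012` scenario stores the Peru-2012 point estimates. Two
storage choices matter:

* the baseline prevalence and the temperature-monitoring effectiveness are
  stored as derivations (`0.122/0.55` and `1 − 0.047/(0.122/0.55)`), not as
  the rounded 22.18 % / 78.81 % usually quoted — cohort counts only
  reproduce from the unrounded values;
* per-person prevention costs are stored as the implied full-precision
  values (strategy prevention totals divided by the 206,298-person cohort:
  64.7159 / 184.8295 / 406.4500), with the familiar rounded integers
  (65/185/406) retained as display metadata. The published totals
  reproduce exactly under this choice and only approximately from the
  rounded integers.

The published sensitivity bounds are stored verbatim rather than
re-derived from the ±30 % convention; for the hospital/outpatient pair the
printed bounds are complements of each other, which the verbatim storage
preserves.

## Costing conventions

Treatment cost per endpoint is unrounded persons × per-episode unit cost.
The outpatient wound-management unit cost is the published US$79 even
though the published line total implies 78.51; the resulting ≤0.1 %
discrepancy in the sub-optimal treatment total is accepted (totals in
millions round identically).

The indirect cost of one premature death is an annuity-due: with
`L = retirement age − mean age at death` years lost and annual wage `w`
(monthly minimum wage / exchange rate × 12),

```
PV = Σ_{t=0}^{⌈L⌉−1}  w_t / (1 + r)^t ,
```

the first lost year undiscounted and a fractional final year pro-rated.
This convention reproduces the published US$6,719 exactly; ordinary-annuity
discounting (first year discounted once) gives ≈6,521 and is rejected. The
monthly wage is derived as PEN 750 / 2.64 = US$284.09, not the rounded
US$284. The value is invariant under joint rescaling of wage and exchange
rate (tested).

## Incremental analysis

ICERs divide unrounded incremental cost by unrounded deaths averted; the
published integers are presentation roundings and are not exactly
reproducible from each other's rounded table cells. Our reconstruction of
the temperature-monitoring vs usual-care ICER lands at 16,114.5 (direct)
and 9,395.6 (with productivity costs) against the published 16,124 and
9,405 — within 0.06 % and 0.10 %; the residual stems from the published
per-episode unit costs being rounded to whole dollars.

Classification: `cost_saving` iff Δcost < 0 and Δdeaths averted > 0 (the
ratio is then never reported as a negative number, per standard practice);
`dominated` iff Δcost > 0 with no health gain; otherwise a numeric ICER.
The willingness-to-pay comparison (`gdp_multiplier × gdp_per_capita`,
default 3×) is inclusive (≤). Including indirect costs shifts the
incremental cost by exactly `−Δdeaths × PV per death` (tested identity).

## One-way sensitivity analysis

Each parameter is set to its low and high bound with all others at base
values. Linked parameters are adjusted to keep the tree coherent, since
the source analysis does not state its rule:

* hospital and outpatient shares are complements of one another;
* varying the amputation-and-heal share holds mortality fixed and assigns
  the remainder to debridement-and-heal, and symmetrically;
* varying mortality rescales the two healing shares proportionally;
* major/minor amputation shares are complements;
* varying the baseline prevalence holds strategy effectiveness fixed
  (strategy prevalences follow); varying an effectiveness holds the
  baseline fixed.

A perturbation that breaks a hard constraint (e.g. a negative residual
probability) flags the entry rather than clamping it. When an excursion
makes a comparison cost-saving, the signed ratio is kept and flagged so
tornado bars remain plottable. The tornado outcome is the ICER by default;
incremental cost and deaths averted are also available. Entries are sorted
by descending swing `|outcome(high) − outcome(low)|`, ties broken by
parameter name for determinism. The default parameter list is every key of
the configured ranges; because the complementary hospital/outpatient pair
are both listed with ranges, they appear as two entries with identical
swings (the tie-break ranks the hospital share first).

## Synthetic scenarios

The generator draws internally consistent parameter sets for property
testing: complementary pairs sampled as complements, the hospital-endpoint
triplet from a Dirichlet distribution (concentration roughly proportional
to the Peru point estimates), costs from uniform ranges, and sensitivity
ranges built as ±30 % brackets clipped to `[0, 1]` for proportions. By
default draws respect the strategy ordering the analysis assumes (each
stronger strategy more effective and more expensive), so dominance labels
are exercised in the same regime; the ordering can be disabled to generate
dominated configurations. Randomness is numpy's `default_rng` (PCG64), so
a seed fixes the draw across platforms.

What the generator does *not* emulate: correlation between epidemiological
parameters, parameter uncertainty distributions suitable for probabilistic
sensitivity analysis, multi-year dynamics, or rural/urban heterogeneity.
Passing property tests therefore demonstrate internal consistency of the
pipeline (conservation, oracle equivalence, identities), not calibration
to any real population.

## Numerical choices and degenerate inputs

Sum-to-one constraints are validated to 1e−9; conservation and oracle
(path-enumeration) equivalence are tested to 1e−9 relative on 1,000 seeded
scenarios. Zero prevalence, zero population, and collapsed sensitivity
ranges all degrade gracefully (zero flows/costs, zero swing). A comparison
with no difference in deaths never divides by zero: it yields a dominance
label or an undefined-ICER entry. Validation reports every violated
constraint in one pass.

## Known limitations

One-year closed cohort: no ulcer recurrence, no multi-year Markov states,
no QALY/DALY weighting, no probabilistic sensitivity analysis, no travel
or waiting-time costs, no rural/urban stratification, Type 2 diabetes
only. These follow the scope of the source analysis; the deliberate
modelling conventions above (annuity-due discounting, implied prevention
unit costs, linked-parameter rules) are this package's own choices where
the source is silent.
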