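# footcea

A decision-tree cost-of-illness and cost-effectiveness model of secondary
prevention of diabetic foot, built around the published Peru-2012 analysis
of three prevention strategies for Type 2 diabetics at high risk of foot
ulceration. It is written for health-economics analysts who want the whole
pipeline — cohort flows, ingredients-based costing, incremental
cost-effectiveness, and one-way sensitivity analysis — as a tested,
scriptable Python library rather than a spreadsheet.

## The model

A one-year, prevalence-based decision tree follows a national high-risk
cohort, `N = population × high-risk fraction`, under one of three
strategies: sub-optimal (usual) care, guideline-based standard care, and
standard care plus daily foot-temperature self-monitoring. Each strategy
*s* has an effectiveness *e(s)* — the fractional reduction in the one-year
ulceration prevalence it achieves — so the ulcer prevalence is

```
p(s) = c · (1 − e(s)),        c = p_ref / (1 − e_ref)
```

where the baseline prevalence *c* is back-calculated from a trial
prevalence observed under an effective strategy. Ulcerated patients heal as
outpatients with probability *e* or are hospitalized with probability *d*;
hospitalized patients heal after debridement (*g*), heal after an
amputation (*f*, split major/minor by *f₁*/*f₂*), or die after an
amputation (*h*), with `f + g + h = 1`.

Direct costs are prevention (per-person package cost × the whole high-risk
cohort) plus treatment (persons at each endpoint × per-episode unit cost,
ingredients-based). Indirect costs value each premature death by the
human-capital approach: the present value of minimum-wage earnings over
the years between the mean age at death and retirement, discounted as an
annuity-due. Strategies are compared by the incremental cost-effectiveness
ratio, `ICER = Δcost / Δdeaths averted`, classified as cost-saving when the
intervention is cheaper and better, and judged against the conventional
threshold of three times GDP per capita. One-way sensitivity analysis
varies each parameter across its configured range (adjusting linked
probabilities to preserve the sum-to-one constraints) and orders parameters
by the swing in the chosen outcome — the tornado diagram.

## A worked example

```python
from footcea import Strategy, compare, peru_2012, total_direct_cost

ps = peru_2012()                       # the bundled Peru-2012 scenario
for s in Strategy:
    print(s.value, round(total_direct_cost(ps, s).direct_total / 1e6, 1))
c = compare(ps, Strategy.STANDARD_PLUS_TEMP, Strategy.SUB_OPTIMAL)
print(round(c.deaths_averted), round(c.icer_direct))
```

prints

```
sub_optimal 74.5
standard 71.8
standard_plus_temp 96.8
1385 16115
```

— the one-year direct cost of illness in millions of US$ under each
strategy (usual care costs US$74.5M; standard care is cheaper overall at
US$71.8M despite a costlier prevention package, because it prevents
expensive hospital episodes), and the headline comparison: adding
temperature monitoring to standard care averts 1,385 deaths a year at
roughly US$16,100 per death averted, under the US$19,704 cost-effectiveness
threshold. The `examples/` directory has one short script per capability:
cost of illness, cost-effectiveness, tornado analysis, and synthetic
scenario generation.

A thin CLI wraps the same functions:

```sh
footcea run --config peru_2012 --out-dir out/          # COI + CEA reports
footcea owsa --intervention standard --comparator sub_optimal --plot
footcea synth --seed 7 --out scenario.yaml             # random valid scenario
footcea validate --config scenario.yaml
```

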