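"""Cost of illness: direct costs of prevention plus treatment, per strategy.

Loads the bundled Peru-2012 scenario, propagates the 206,298-person
high-risk cohort through the decision tree for each prevention strategy,
and prices every endpoint. The totals are the one-year direct economic
burden of diabetic foot under each strategy.
"""

from footcea import Strategy, compute_flows, peru_2012, summarize_outcomes, total_direct_cost

ps = peru_2012()

for strategy in Strategy:
    flows = compute_flows(ps, strategy)
    outcomes = summarize_outcomes(flows)
    costs = total_direct_cost(ps, strategy)
    print(f"\n{strategy.value}")
    print(f"  ulcerated persons        {flows.n_ulcerated:12,.0f}")
    print(f"  deaths                   {outcomes.deaths:12,.0f}")
    print(f"  prevention cost          {costs.prevention_total:12,.0f} US$")
    print(f"  treatment cost           {costs.treatment_total:12,.0f} US$")
    print(f"  total direct cost        {costs.direct_total:12,.0f} US$"
          f"  ({costs.direct_total / 1e6:.1f} M)")

# The sub-optimal (usual-care) burden is ~US$74.5M/year; standard care is
# cheaper overall (~US$71.8M) despite costing more to deliver, because it
# prevents most of the expensive hospital episodes.
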