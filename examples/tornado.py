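"""One-way sensitivity analysis: which parameters move the ICER most.

Each parameter with a configured range is set to its low and high bound in
turn (linked probabilities adjusted to keep the tree consistent) and the
ICER against sub-optimal care recomputed. The swing — the spread between
the two excursions — orders the tornado diagram.
"""

from footcea import OwsaSpec, Strategy, peru_2012, run_owsa

ps = peru_2012()
spec = OwsaSpec(
    intervention=Strategy.STANDARD_PLUS_TEMP,
    comparator=Strategy.SUB_OPTIMAL,
    outcome="icer_direct",
)

print("temperature monitoring vs sub-optimal care, ICER (US$/death averted)\n")
print(f"{'parameter':42s} {'low':>10s} {'high':>10s} {'swing':>10s}")
for e in run_owsa(ps, spec):
    lo = f"{e.outcome_at_low:,.0f}" if e.outcome_at_low is not None else "n/a"
    hi = f"{e.outcome_at_high:,.0f}" if e.outcome_at_high is not None else "n/a"
    print(f"{e.parameter:42s} {lo:>10s} {hi:>10s} {e.swing:10,.0f}")

# The per-person cost of the prevention package dominates; the baseline
# ulcer prevalence and the share of ulcers needing hospital care come next.
# Parameters not involved in this comparison show zero swing.
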