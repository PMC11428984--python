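"""Elicit category weights from a simulated expert panel.

Nine experts start from the default category percentages with ±5-point
disagreement; iterated Delphi rounds (median aggregation, each expert
moving halfway toward the consensus) shrink the interquartile range below
0.1, and the consensus is split into per-test maxima.
"""

from apsi import (
    allocate_budgets,
    category_counts,
    default_battery,
    default_scheme,
    delphi_converge,
    generate_expert_panel,
)

state = generate_expert_panel(9, default_scheme(), disagreement_sd=5.0, seed=7)
print("initial per-category IQR:")
print(state.dispersion.round(2).to_string())

outcome = delphi_converge(state, tolerance=0.1, max_rounds=50, contraction=0.5)
print(f"\nconverged: {outcome.converged} after {outcome.rounds} rounds")
print("consensus weights (percent):")
for cat, w in outcome.scheme.weights.items():
    print(f"  {cat:15s} {w:6.2f}")

per_test = allocate_budgets(outcome.scheme, category_counts(default_battery()))
print("\nper-test maxima (equal split within category):")
for cat, m in per_test.items():
    print(f"  {cat:15s} {m:6.2f}")

# The consensus stays close to the baseline the experts were drawn around;
# each category's percentage divided by its number of tests gives the
# points a single assay can contribute to the 100-point index.
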