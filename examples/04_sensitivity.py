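"""Scenario, one-way and probabilistic sensitivity analysis.

Runs the full robustness layer on a synthetic market: the no-discount
and no-volume-weighting scenarios, the three one-way variations as a
tornado table, and a 1000-draw Monte Carlo PSA with percentile CI.
"""

from biosimbia import (
    OneWayParameter,
    PSAConfig,
    ScenarioVariant,
    SyntheticMarketConfig,
    compute_bia,
    generate_market,
    run_one_way,
    run_psa,
    run_scenario,
    tornado_table,
)

market = generate_market(SyntheticMarketConfig(seed=42, n_molecules=5))
base = compute_bia(market.inputs)
print(f"base case total savings: {base.total_savings() / 1e6:.2f} EUR million")

for variant in (ScenarioVariant.no_discounts, ScenarioVariant.no_volume_weighting):
    res = run_scenario(variant, market.inputs)
    print(f"  scenario {variant.value:20s}: {res.total_savings() / 1e6:10.2f} EUR million")

one_way = {p.value: run_one_way(p, market.inputs, share_molecule="M00") for p in OneWayParameter}
print()
print("tornado (totals in EUR million, widest range first):")
table = tornado_table(one_way, base.total_savings())
for col in table.columns[1:]:
    table[col] = (table[col] / 1e6).round(2)
print(table.to_string(index=False))

psa = run_psa(market.inputs, PSAConfig(seed=7, n_simulations=1000))
t = psa.summary.loc["TOTAL"] / 1e6
print()
print(
    f"PSA total savings: mean {t['mean']:.2f} "
    f"(95% CI {t['ci_low']:.2f} - {t['ci_high']:.2f}) EUR million"
)
print(
    "\nDropping tender discounts roughly halves the savings, the dominant\n"
    "uncertainty in this model; the PSA mean stays close to the base case\n"
    "because every varied parameter is centred on its base value."
)
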