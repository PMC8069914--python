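# biosimbia

Retrospective budget impact analysis (BIA) of biosimilar market entry,
built as a reusable, tested Python library. It reconstructs what a
third-party payer actually paid for off-patent biologicals — regulated
list prices eroded by a reference-price system, then discounted through
hospital tenders — and compares that against a counterfactual market
without biosimilars, where the originator keeps its pre-entry price and
all demand. The package targets health economists and pharmaceutical
policy analysts who need payer-perspective savings estimates with a full
deterministic and probabilistic sensitivity layer, and who cannot ship
confidential consumption or tender data alongside their model: every
stage is exercised end to end on synthetic markets with exact,
independently computed ground truth.

## The model

For each molecule *m* and year *t*, consumption is measured in WHO
defined daily doses (DDD), split between originator and biosimilar
product classes. Savings are the difference between two scenarios
evaluated on the **same** demand:

```
S(m,t) = C_without(m,t) − C_with(m,t)

C_without(m,t) = [Q_org(m,t) + Q_bio(m,t)] · p*(m)
C_with(m,t)    = Σ_c  Q_c(m,t) · p̄_c(m,t) · [1 − d_c(m,t)]
```

where `Q_c` is annual DDD volume of class `c`, `p*` is the originator
list price (EUR/DDD) frozen at the month before the first biosimilar
launch, `p̄_c` is the spreading-weighted mean of the monthly list price
of class `c` (annual volume spread uniformly over the months in which
the class is priced, so mid-year reference-price changes are pro-rated),
and `d_c` is the commercial discount fraction.

Monthly list prices follow the reference-price system: the ex-factory
price (EFP) holds until a reference-price order (RPO) takes effect — in
its publication month if published before the 15th, otherwise the next
month — after which originator and biosimilar share the reference price
(RP). An unobserved biosimilar price between launch and its first RPO is
imputed as RP × 1.10.

Discounts are estimated per molecule, class and year from tender awards
as `1 − Σ v·p / Σ v·L` (volume-weighted purchase price against the list
price prevailing at each award month), with award volumes apportioned
over contract years. Years without tender coverage are backfilled by a
least-squares line constrained through zero discount the year before the
first biosimilar launch. Retail-channel molecules carry no discount.

The sensitivity layer provides the no-discount and no-volume-weighting
scenarios, one-way variations (pre-RPO price ±50%, RPO month ±1,
a molecule's biosimilar share ±20%), and a 1000-draw Monte Carlo PSA
over per-molecule-year prices, discounts and shares with percentile
confidence intervals.

## Worked example

`examples/05_published_table.py` feeds the published 13-molecule
scenario-cost table of the Spanish 2009–2019 analysis through the
aggregation layer:

```
       cost_without  cost_with  savings
SOM          992.50     617.32   375.18
EPO          993.01     403.86   589.15
INF         1054.47     604.18   450.29
...
TOTAL       6832.64    4526.13  2306.51

total savings            :  2306.51 EUR million
top-3 (SOM+EPO+INF) share:    61.33 %
adalimumab (ADA) share   :     7.97 %
```

Savings are recomputed as the row-wise cost difference and the TOTAL row
as full-precision column sums; the 2306.51 differs from the published
2306.48 only by row rounding of the printed inputs. Somatropin, epoetin
and infliximab together carry over 60% of the 11-year savings.

The other examples generate a synthetic market and run each capability:

- `01_base_case.py` — two-scenario costing against the brute-force oracle;
- `02_price_timeline.py` — EFP/RP timeline, day-15 rule, pre-RPO imputation;
- `03_discount_estimation.py` — weighted tender discounts and anchored backfill;
- `04_sensitivity.py` — scenarios, tornado table, seeded Monte Carlo PSA.

A thin CLI wraps the same functions for shell use:

```bash
biosimbia simulate --out market/ --seed 11     # synthetic inputs + ground truth
biosimbia run --inputs market/ --out reports/  # base-case report tables
biosimbia sa  --inputs market/ --out reports/  # scenarios + tornado
biosimbia psa --inputs market/ --out reports/ --seed 7
```

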