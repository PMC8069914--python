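# Methods

## Scope and perspective

The package estimates the budget impact of biosimilar competition from a
third-party payer perspective: direct pharmacological costs only, no
health outcomes, no patient-level modelling. Two scenarios are costed on
identical consumption: the actual market (biosimilars present, list
prices eroded by the reference-price system, hospital purchases
discounted through tenders) and a counterfactual without biosimilars
(the originator keeps its pre-entry list price and absorbs all demand).
Savings are the cost difference, reported per molecule, per year and in
total. All computation is done in EUR at full precision; EUR-million
rounding to two decimals happens only in the rendering layer.

## Price model

Prices are carried in EUR per WHO defined daily dose (DDD); unit-level
inputs are converted on ingest via per-presentation DDD factors. The
monthly list price is piecewise constant: ex-factory prices (EFP)
forward-fill from their effective month, and a reference-price order
(RPO) replaces them with the reference price (RP) — shared by originator
and biosimilar — from its effective month. An RPO published strictly
before the 15th of a month applies that same month, otherwise the next
month; the day-15 cutoff and a ±1-month shift are configuration knobs
used by the one-way analysis. An RP above the prevailing EFP is treated
as a no-op cap with a warning rather than a price increase.

When a biosimilar has no observed price between its launch and the first
RPO effective month, those months are imputed at RP × (1 + 10%), the
markup observed on molecules with complete price histories; the markup
and an extra ±50% factor are configurable. The counterfactual freezes
the originator EFP in force at the month before the first biosimilar
launch; for molecules whose biosimilar predates the analysis horizon the
freeze falls back to the earliest available originator price, since no
pre-launch observation exists inside the data window.

## Discount model

The commercial discount for a molecule, class and year is the
volume-weighted gap between tender purchase prices and the list price
(EFP or RP) prevailing at each award month:
`d = 1 − Σ v·p / Σ v·L`. In the base case an award's volume is
apportioned uniformly over the months its contract covers, so multi-year
contracts contribute to every covered year; the no-volume-weighting
scenario attributes the whole volume to the award year instead. Tender
prices are quoted per unit without a presentation id; the molecule's
mean DDD-per-unit factor converts the list price for comparison, and
since the discount is a price ratio any consistent conversion cancels.
A weighted discount below zero (bids above list) clamps to zero with a
logged warning.

Years without observations are backfilled by least squares constrained
through zero discount at the anchor year (the year before the first
biosimilar launch): `β = Σ tᵢdᵢ / Σ tᵢ²` with `tᵢ` the year offset from
the anchor. Predictions are clamped to [0, 0.95]; the cap prevents
nonsensical ≥100% extrapolations while leaving the open-ended top
reporting band (">50%") reachable. Observed years always override the
fit. An ordinary-least-squares variant that treats the anchor as a
pseudo-observation is available (`regression_method="ols_pseudo"`); with
a single anchor point both fits coincide. A product class with no
observations at all (e.g. a biosimilar that never sold) receives a zero
series with a warning — it has no volume to discount — while a hospital
molecule with no observations in either class is an error. Retail
molecules always carry zero discounts (no tender channel).

## Costing

Annual DDD volumes are spread uniformly over the months in which the
class is priced, so a molecule entering mid-year contributes from its
first priced month (earlier months are zero, not missing) and mid-year
RP changes are pro-rated. A year-start spreading convention is available
for sensitivity use. Consumption in a year where a class has no priced
month at all is an error, never silently dropped. Demand is conserved
across scenarios by construction, and the aggregation identities
(savings = cost difference row-wise and in every aggregate) hold to
machine precision.

## Sensitivity layer

Deterministic scenarios: `no_discounts` zeroes every discount while
keeping RP erosion (the minimum-savings scenario); `no_volume_weighting`
switches tender attribution as above. One-way variations move the
imputed pre-RPO price ±50%, every RPO effective month ∓1, and a chosen
molecule's biosimilar DDD share in chosen years ±20% (total demand
conserved, share clamped to [0, 1]); variations with nothing to act on
return the base case with a warning. Note that the RPO-month variation
re-estimates discounts against the shifted list prices — the full
pipeline is re-run — so its effect on savings combines the price-path
effect with a discount-reestimation effect and need not be monotone in
the shift.

The probabilistic analysis draws, per simulation, one multiplier per
molecule-year and parameter family — prices (applied to both scenarios'
prices of that molecule-year), discounts (both classes, capped at 0.95)
and biosimilar share (demand conserved) — from a normal distribution
centred at 1 and truncated to the valid range by rejection sampling.
Relative standard deviations default to 10% per family; the source
analysis states normal distributions but neither SDs nor truncation, so
these defaults are a package convention, fully configurable. Summaries
are the mean and percentile (2.5%, 97.5%) interval, chosen over a normal
approximation because savings distributions are asymmetric under
truncation. Reproducibility: one root seed, one spawned substream per
simulation, so results are independent of iteration order and bitwise
stable. Because total demand is conserved, a molecule's total DDD volume
is identical across draws; the savings-versus-consumption scatter
produced from the draws disperses vertically only.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
biosimilar entry 20–30% below the originator list price; one RPO within
6–12 months of launch fixing the RP at the entry price; S-shaped
(logistic) uptake `ceiling / (1 + exp(−rate·(t − midpoint)))` with
defaults (ceiling 0.5–0.9, rate 0.6–1.2, midpoint 2–4 years) giving
roughly half the ceiling by year 3–4; annual demand with mild growth;
and calendar-year tenders whose purchase prices realize a configured
discount tier (low/medium/high mapping to the 0–25% / 25–50% / >50%
reporting bands) with ±5% price noise, clamped so bids never exceed
list. Tier targets are drawn strictly inside their band so the noise
cannot push a weighted discount across a band edge. About 40% of
molecules omit the biosimilar entry price record to exercise the
pre-RPO imputation path, and launches may predate the horizon to
exercise the freeze-at-start convention. By default every post-launch
year has tender coverage, so discount backfill is exercised by dedicated
tests rather than by generated markets.

Every market carries exact ground-truth savings computed at generation
time by a deliberately naive month-by-month, scalar-loop accumulator
that re-derives prices, discounts and costs from the interchange tables
without reusing engine code. What the generator does **not** emulate:
real uptake heterogeneity across molecules and regions, EFP revisions
between RPO rounds, multi-year or overlapping tender contracts in the
default configuration, and demand responses to price. Passing tests
therefore demonstrate internal correctness of the model's arithmetic and
logic, not fidelity to any particular national market.

## Numerical choices

Savings are differences of costs accumulated to ~1e9, so engine–oracle
agreement is asserted at 1e-9 relative to the accumulated cost scale
(in practice ~1e-15); a per-cell relative measure would be meaningless
for near-zero savings cells. Report tables write full precision by
default so `read(write(x)) == x`; presentation rounding is opt-in.
Ties and degenerate inputs: a zero-volume molecule-year costs zero in
both scenarios; an undefined uptake share (zero total volume) is NaN and
excluded from means; truncated-normal rejection fails loudly if bounds
are unreachable for the configured SD.

## Problem sizes

The validation suite runs the engine–oracle comparison on 50 seeded
markets of 4 molecules over 2009–2019 and the PSA checks at 1000
simulations, sizes at which every distributional check is already
stable; all defaults scale to larger markets linearly in
molecules × months.

## Known limitations

- The headline historical results depend on confidential consumption,
  price and tender inputs; only the published per-molecule table can be
  reproduced, by aggregation arithmetic.
- Discounts before the first tender observations rest on the anchored
  linear backfill, an assumption, not data.
- The model works at EFP/RP level: retail margins and VAT are out of
  scope, as are regional differences in tendering.
- PSA dispersion reflects the package's SD conventions, not empirically
  estimated parameter uncertainty.
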