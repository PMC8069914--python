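"""Synthetic biosimilar markets with known ground-truth savings.

The generator emulates the statistical structure the analysis assumes:
a biosimilar enters 20–30% below the originator list price, the
reference-price order lands within a year of launch and pulls both
classes down to the biosimilar entry price, uptake follows an S-shaped
(logistic) adoption curve, and hospital tenders realize a configured
discount tier (low 0–25%, medium 25–50%, high >50%) with price noise.

Every generated market carries exact per-molecule-year savings computed
at generation time by a deliberately naive month-by-month accumulator,
structurally independent of the costing engine, so the engine can be
checked against it to high precision on any seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .market_model import AnalysisHorizon, Channel, MarketInputs, MoleculeSpec, ProductClass

__all__ = [
    "MoleculeScenario",
    "SyntheticMarketConfig",
    "SyntheticMarket",
    "logistic_uptake",
    "generate_market",
    "brute_force_savings",
    "fixture_from_table1",
    "TABLE1_CODES",
]

# Discount-tier target bands, kept strictly inside the reporting bands so
# that ±5% tender price noise cannot push a weighted discount outside its
# configured tier.
_TIER_TARGETS = {"low": (0.08, 0.20), "medium": (0.30, 0.45), "high": (0.55, 0.65)}


def logistic_uptake(
    years_since_launch: float, ceiling: float, rate: float, midpoint: float
) -> float:
    """S-shaped biosimilar share: ceiling / (1 + exp(−rate·(t − midpoint)))."""
    if not (0.0 <= ceiling <= 1.0):
        raise ValueError(f"ceiling {ceiling} outside [0, 1]")
    if not rate > 0:
        raise ValueError(f"rate must be positive, got {rate}")
    return ceiling / (1.0 + math.exp(-rate * (years_since_launch - midpoint)))


@dataclass
class MoleculeScenario:
    """Generator parameters for one synthetic molecule market."""

    code: str
    channel: Channel
    launch: pd.Period                  # first biosimilar year-month
    originator_price: float            # EUR/DDD list price level
    entry_rebate: float                # biosimilar entry price = orig × (1 − rebate)
    rpo_lag_months: int                # RPO publication lag after launch (≤ 12)
    rpo_day: int                       # publication day-of-month
    biosimilar_price_observed: bool    # False → pre-RPO price must be imputed
    uptake_ceiling: float
    uptake_rate: float
    uptake_midpoint: float
    base_demand_ddd: float
    demand_growth: float
    discount_tier_originator: str
    discount_tier_biosimilar: str
    tenders_per_year: int
    ddd_per_unit: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.entry_rebate < 1.0):
            raise ValueError("entry_rebate must lie in [0, 1)")
        if self.rpo_lag_months > 12:
            raise ValueError("rpo_lag_months must be <= 12 (RPS applies within a year)")
        for tier in (self.discount_tier_originator, self.discount_tier_biosimilar):
            if tier not in _TIER_TARGETS:
                raise ValueError(f"unknown discount tier {tier!r}")


@dataclass
class SyntheticMarketConfig:
    seed: int
    n_molecules: int = 6
    horizon: AnalysisHorizon = field(default_factory=lambda: AnalysisHorizon(2009, 2019))
    retail_fraction: float = 0.2
    rebate_range: tuple[float, float] = (0.20, 0.30)
    unobserved_price_fraction: float = 0.4
    tenders_per_year: int = 2
    molecules: list[MoleculeScenario] | None = None  # explicit override


@dataclass
class SyntheticMarket:
    """Generated input tables plus oracle-computed ground truth."""

    inputs: MarketInputs
    scenarios: list[MoleculeScenario]
    ground_truth: pd.DataFrame  # (code, year) -> cost_without, cost_with, savings


def _random_scenarios(config: SyntheticMarketConfig) -> list[MoleculeScenario]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5C3]))
    h = config.horizon
    out = []
    for i in range(config.n_molecules):
        retail = rng.random() < config.retail_fraction
        launch_year = int(rng.integers(h.start_year - 2, h.end_year))  # may predate horizon
        launch = pd.Period(f"{launch_year}-{int(rng.integers(1, 13)):02d}", freq="M")
        tier = str(rng.choice(["low", "medium", "high"]))
        out.append(
            MoleculeScenario(
                code=f"M{i:02d}",
                channel=Channel.retail if retail else Channel.hospital,
                launch=launch,
                originator_price=float(np.exp(rng.uniform(np.log(2.0), np.log(300.0)))),
                entry_rebate=float(rng.uniform(*config.rebate_range)),
                rpo_lag_months=int(rng.integers(6, 13)),
                rpo_day=int(rng.integers(1, 29)),
                biosimilar_price_observed=bool(
                    rng.random() > config.unobserved_price_fraction
                ),
                uptake_ceiling=float(rng.uniform(0.5, 0.9)),
                uptake_rate=float(rng.uniform(0.6, 1.2)),
                uptake_midpoint=float(rng.uniform(2.0, 4.0)),
                base_demand_ddd=float(np.exp(rng.uniform(np.log(1e5), np.log(5e6)))),
                demand_growth=float(rng.uniform(0.0, 0.08)),
                discount_tier_originator="low",
                discount_tier_biosimilar=tier,
                tenders_per_year=config.tenders_per_year,
                ddd_per_unit=float(rng.uniform(0.5, 30.0)),
            )
        )
    return out


def _annual_shares(ms: MoleculeScenario, horizon: AnalysisHorizon) -> dict[int, float]:
    """Mid-year logistic share per horizon year; zero before launch."""
    launch_decimal = ms.launch.year + (ms.launch.month - 1) / 12.0
    shares = {}
    for year in horizon.years:
        year = int(year)
        t = (year + 0.5) - launch_decimal
        if year < ms.launch.year or t <= 0:
            shares[year] = 0.0
        else:
            shares[year] = logistic_uptake(t, ms.uptake_ceiling, ms.uptake_rate, ms.uptake_midpoint)
    return shares


def generate_market(config: SyntheticMarketConfig) -> SyntheticMarket:
    """Generate a full synthetic market, reproducible under the seed."""
    scenarios = config.molecules or _random_scenarios(config)
    h = config.horizon
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E4]))

    molecules: dict[str, MoleculeSpec] = {}
    uptake_rows, price_rows, rpo_rows, tender_rows = [], [], [], []

    for ms in scenarios:
        molecules[ms.code] = MoleculeSpec(
            code=ms.code,
            name=f"synthetic molecule {ms.code}",
            channel=ms.channel,
            first_biosimilar_year_month=ms.launch,
            ddd_per_unit={"P1": ms.ddd_per_unit},
            discount_applicable=ms.channel is Channel.hospital,
        )
        entry_price = ms.originator_price * (1.0 - ms.entry_rebate)

        # list prices: originator flat from horizon start; biosimilar entry
        # price observed for a subset of molecules only
        price_rows.append(
            (ms.code, "originator", str(h.months[0]), ms.originator_price)
        )
        if ms.biosimilar_price_observed:
            eff = max(ms.launch, h.months[0])
            price_rows.append((ms.code, "biosimilar", str(eff), entry_price))

        # one RPO within a year of launch fixing the RP at the entry price
        pub = ms.launch + ms.rpo_lag_months
        rpo_rows.append(
            (ms.code, f"{pub.year:04d}-{pub.month:02d}-{ms.rpo_day:02d}", entry_price)
        )

        shares = _annual_shares(ms, h)
        for year in h.years:
            year = int(year)
            total_ddd = ms.base_demand_ddd * (1.0 + ms.demand_growth) ** (year - h.start_year)
            s = shares[year]
            ddd_b = total_ddd * s
            ddd_o = total_ddd - ddd_b
            uptake_rows.append((ms.code, year, "originator", ddd_o / ms.ddd_per_unit, "P1"))
            uptake_rows.append((ms.code, year, "biosimilar", ddd_b / ms.ddd_per_unit, "P1"))

        if ms.channel is Channel.hospital:
            tender_rows.extend(
                _tenders_for(ms, shares, h, rng)
            )

    inputs = MarketInputs(
        horizon=h,
        molecules=molecules,
        uptake=pd.DataFrame(
            uptake_rows, columns=["code", "year", "product_class", "units", "presentation_id"]
        ),
        prices=_price_frame(price_rows),
        rpo_events=pd.DataFrame(
            [(c, pd.Timestamp(d), rp) for c, d, rp in rpo_rows],
            columns=["code", "publication_date", "rp_per_ddd"],
        ),
        tenders=_tender_frame(tender_rows),
    )
    truth = brute_force_savings(inputs)
    return SyntheticMarket(inputs=inputs, scenarios=scenarios, ground_truth=truth)


def _price_frame(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c, pc, pd.Period(m, freq="M"), p) for c, pc, m, p in rows],
        columns=["code", "product_class", "effective_month", "efp_per_ddd"],
    )


def _tender_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(
            columns=[
                "tender_id", "code", "product_class", "award_date", "contract_start",
                "contract_end", "purchase_price_per_unit", "volume_units", "region",
            ]
        )
    return pd.DataFrame(rows)


def _tenders_for(
    ms: MoleculeScenario,
    shares: dict[int, float],
    h: AnalysisHorizon,
    rng: np.random.Generator,
) -> list[dict]:
    """Calendar-year tenders realizing the configured discount tiers.

    Purchase prices target a tier-specific discount with uniform ±5%
    noise, clamped so bids never exceed the prevailing list price.
    """
    rows = []
    first_year = max(ms.launch.year, h.start_year)
    for year in range(first_year, h.end_year + 1):
        total_ddd = ms.base_demand_ddd * (1.0 + ms.demand_growth) ** (year - h.start_year)
        s = shares[year]
        class_units = {
            "originator": (1.0 - s) * total_ddd / ms.ddd_per_unit,
            "biosimilar": s * total_ddd / ms.ddd_per_unit,
        }
        tiers = {
            "originator": ms.discount_tier_originator,
            "biosimilar": ms.discount_tier_biosimilar,
        }
        for pclass, units in class_units.items():
            if units <= 0:
                continue
            first_month = 1
            if pclass == "biosimilar" and year == ms.launch.year:
                first_month = ms.launch.month
            for k in range(ms.tenders_per_year):
                month = int(rng.integers(first_month, 13))
                day = int(rng.integers(1, 29))
                award_month = pd.Period(f"{year}-{month:02d}", freq="M")
                list_per_ddd = _oracle_price(ms, pclass, award_month, h)
                assert list_per_ddd is not None
                list_per_unit = list_per_ddd * ms.ddd_per_unit
                lo, hi = _TIER_TARGETS[tiers[pclass]]
                target = float(rng.uniform(lo, hi))
                price = list_per_unit * (1.0 - target) * float(rng.uniform(0.95, 1.05))
                price = min(price, list_per_unit)
                rows.append(
                    {
                        "tender_id": f"{ms.code}-{year}-{pclass[:4]}-{k}",
                        "code": ms.code,
                        "product_class": pclass,
                        "award_date": pd.Timestamp(year=year, month=month, day=day),
                        "contract_start": pd.Period(f"{year}-01", freq="M"),
                        "contract_end": pd.Period(f"{year}-12", freq="M"),
                        "purchase_price_per_unit": price,
                        "volume_units": units * float(rng.uniform(0.05, 0.2)),
                        "region": "",
                    }
                )
    return rows


# --------------------------------------------------------------------------
# Brute-force oracle
#
# A deliberately naive scalar re-derivation of the model: prices by
# scanning event lists month by month, discounts by explicit per-tender
# loops, costs by month-level accumulation. No engine code is reused.


def _oracle_rpo_effective(ms: MoleculeScenario) -> pd.Period:
    pub = ms.launch + ms.rpo_lag_months
    eff = pub
    if ms.rpo_day >= 15:
        eff = eff + 1
    return eff


def _oracle_price(
    ms: MoleculeScenario, pclass: str, month: pd.Period, h: AnalysisHorizon
) -> float | None:
    """Actual-scenario list price by first principles for generated markets."""
    entry = ms.originator_price * (1.0 - ms.entry_rebate)
    eff = _oracle_rpo_effective(ms)
    if pclass == "originator":
        price = ms.originator_price
        if month >= eff:
            price = min(price, entry)  # RP replaces when not above EFP
        return price
    # biosimilar
    if month < ms.launch:
        return None
    if month >= eff:
        return entry
    if ms.biosimilar_price_observed:
        return entry
    return entry * 1.10  # pre-RPO imputation: 10% over the first RP


def brute_force_savings(inputs: MarketInputs) -> pd.DataFrame:
    """Independent month-by-month accumulation of both scenarios' costs.

    Works directly on the interchange tables with plain Python loops and
    the same model conventions as the engine (day-15 RPO rule, RP
    replacement, 10% pre-RPO imputation, uniform within-year spreading
    over priced months, volume-weighted tender discounts on calendar
    attribution, anchored regression backfill, frozen counterfactual).
    """
    h = inputs.horizon
    months = list(h.months)
    rows = []
    for code, spec in inputs.molecules.items():
        efp = inputs.prices[inputs.prices["code"] == code]
        rpos = inputs.rpo_events[inputs.rpo_events["code"] == code]
        tenders = inputs.tenders[inputs.tenders["code"] == code]
        factor = spec.mean_ddd_factor()

        # event lists
        efp_events = {
            pc.value: sorted(
                (r["effective_month"], float(r["efp_per_ddd"]))
                for _, r in efp[efp["product_class"] == pc.value].iterrows()
            )
            for pc in ProductClass
        }
        rp_events = []
        for _, r in rpos.iterrows():
            ts = pd.Timestamp(r["publication_date"])
            effm = pd.Period(ts, freq="M")
            if ts.day >= 15:
                effm += 1
            rp_events.append((effm, float(r["rp_per_ddd"])))
        rp_events.sort()
        first_rp = rp_events[0] if rp_events else None

        def list_price(pclass: str, m: pd.Period) -> float | None:
            efp_val = None
            for em, v in efp_events[pclass]:
                if em <= m:
                    efp_val = v
            rp_val = None
            for em, v in rp_events:
                if em <= m:
                    rp_val = v
            if pclass == "biosimilar" and m < spec.first_biosimilar_year_month:
                return None
            price = efp_val
            if rp_val is not None and (price is None or rp_val <= price):
                price = rp_val
            if (
                pclass == "biosimilar"
                and price is None
                and first_rp is not None
                and m < first_rp[0]
                and m >= spec.first_biosimilar_year_month
            ):
                price = first_rp[1] * 1.10
            return price

        # annual DDD volumes per class
        ddd: dict[tuple[int, str], float] = {}
        for _, r in inputs.uptake[inputs.uptake["code"] == code].iterrows():
            pres = r["presentation_id"] or ""
            f = spec.ddd_per_unit[pres] if pres else next(iter(spec.ddd_per_unit.values()))
            key = (int(r["year"]), r["product_class"])
            ddd[key] = ddd.get(key, 0.0) + float(r["units"]) * f

        # tender-derived discounts, then anchored regression backfill
        discount: dict[tuple[int, str], float] = {}
        if spec.channel is Channel.hospital and spec.discount_applicable:
            for pclass in ("originator", "biosimilar"):
                observed: dict[int, float] = {}
                for year in h.years:
                    year = int(year)
                    num = den = 0.0
                    for _, t in tenders[tenders["product_class"] == pclass].iterrows():
                        start, end = t["contract_start"], t["contract_end"]
                        n_total = (end - start).n + 1
                        y0 = max(start, pd.Period(f"{year}-01", freq="M"))
                        y1 = min(end, pd.Period(f"{year}-12", freq="M"))
                        overlap = (y1 - y0).n + 1 if y0 <= y1 else 0
                        if overlap == 0:
                            continue
                        vol = float(t["volume_units"]) * overlap / n_total
                        lp = list_price(pclass, pd.Period(t["award_date"], freq="M"))
                        num += vol * float(t["purchase_price_per_unit"])
                        den += vol * lp * factor
                    if den > 0:
                        observed[year] = max(0.0, 1.0 - num / den)
                for _, t in inputs.discount_overrides[
                    (inputs.discount_overrides["code"] == code)
                    & (inputs.discount_overrides["product_class"] == pclass)
                ].iterrows():
                    observed[int(t["year"])] = float(t["discount_fraction"])
                anchor = spec.launch_year - 1
                st = sd = 0.0
                for y, d in observed.items():
                    st += (y - anchor) * (y - anchor)
                    sd += (y - anchor) * d
                beta = sd / st if st > 0 else 0.0
                for year in h.years:
                    year = int(year)
                    if year in observed:
                        discount[(year, pclass)] = observed[year]
                    else:
                        discount[(year, pclass)] = min(0.95, max(0.0, beta * (year - anchor)))
        else:
            for year in h.years:
                for pclass in ("originator", "biosimilar"):
                    discount[(int(year), pclass)] = 0.0

        # counterfactual frozen price: originator EFP in force the month
        # before launch, else the earliest available record
        freeze_month = max(spec.first_biosimilar_year_month - 1, months[0])
        frozen = None
        for em, v in efp_events["originator"]:
            if em <= freeze_month:
                frozen = v
        if frozen is None and efp_events["originator"]:
            frozen = efp_events["originator"][0][1]

        for year in h.years:
            year = int(year)
            cost_with = 0.0
            total_year_ddd = 0.0
            for pclass in ("originator", "biosimilar"):
                vol = ddd.get((year, pclass), 0.0)
                total_year_ddd += vol
                if vol == 0.0:
                    continue
                priced_months = [
                    m for m in months
                    if m.year == year and list_price(pclass, m) is not None
                ]
                for m in priced_months:
                    cost_with += (
                        (vol / len(priced_months))
                        * list_price(pclass, m)
                        * (1.0 - discount[(year, pclass)])
                    )
            cost_without = total_year_ddd * frozen
            rows.append((code, year, cost_without, cost_with, cost_without - cost_with))

    return pd.DataFrame(
        rows, columns=["code", "year", "cost_without", "cost_with", "savings"]
    ).set_index(["code", "year"]).sort_index()


# --------------------------------------------------------------------------
# Printed headline table (published per-molecule scenario costs, EUR million)

TABLE1_CODES = [
    "SOM", "FIL", "EPO", "FOL", "INF", "INS", "ETA", "CHO", "RIT", "TRA",
    "ENO", "ADA", "PEG",
]

_TABLE1_COSTS = {
    # code: (cost without biosimilars, cost with biosimilars), EUR million
    "SOM": (992.50, 617.32),
    "FIL": (469.62, 180.22),
    "EPO": (993.01, 403.86),
    "FOL": (119.20, 64.27),
    "INF": (1054.47, 604.18),
    "INS": (818.41, 707.87),
    "ETA": (628.39, 537.91),
    "CHO": (134.67, 125.34),
    "RIT": (433.39, 318.76),
    "TRA": (140.89, 113.26),
    "ENO": (264.86, 261.25),
    "ADA": (772.46, 588.69),
    "PEG": (10.77, 3.20),
}


def fixture_from_table1() -> pd.DataFrame:
    """Published 13-molecule scenario costs (EUR million), as a cost frame.

    The returned frame carries only the two scenario cost columns; the
    savings column and TOTAL row are recomputed by the aggregation layer
    (:func:`biosimbia.market_model.molecule_summary`), which is exactly
    what the published savings table prints.
    """
    return pd.DataFrame.from_dict(
        _TABLE1_COSTS, orient="index", columns=["cost_without", "cost_with"]
    ).loc[TABLE1_CODES]
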