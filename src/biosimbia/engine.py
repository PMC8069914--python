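"""Two-scenario budget-impact costing on the monthly net-price grid.

The savings attributable to biosimilar competition are the cost
difference between a counterfactual scenario — no biosimilars, the
originator keeps its frozen pre-entry list price and captures all demand
— and the actual scenario, where demand splits between originator and
biosimilar, list prices erode under the reference-price system and
hospital tenders add commercial discounts. Demand (in DDDs) is conserved
across the two scenarios; only prices and market split differ.

Annual consumption is spread uniformly over the months in which a
product class is priced, so mid-year reference-price effects are
pro-rated; a year-start convention is available for sensitivity use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discounts import DiscountSeries, assemble_discount_series
from .errors import ReferentialError, UnpriceableError
from .market_model import (
    AnalysisHorizon,
    CLASSES,
    MarketInputs,
    MoleculeSpec,
    ProductClass,
)
from .pricing import (
    PricingConfig,
    build_price_timeline,
    counterfactual_price_timeline,
)

__all__ = [
    "EngineConfig",
    "convert_units_to_ddd",
    "uptake_share",
    "cost_actual_scenario",
    "cost_counterfactual_scenario",
    "prepare_market",
    "compute_bia",
    "BIAResult",
    "savings_share",
    "savings_vs_total_spend",
]


@dataclass(frozen=True)
class EngineConfig:
    """Model configuration shared by the base case and its variants."""

    spreading: str = "uniform"          # "uniform" | "year_start"
    pricing: PricingConfig = field(default_factory=PricingConfig)
    spread_over_contract: bool = True   # tender volume apportioned over contract years
    discounts_enabled: bool = True
    regression_method: str = "constrained"

    def __post_init__(self) -> None:
        if self.spreading not in ("uniform", "year_start"):
            raise ValueError(f"unknown spreading convention {self.spreading!r}")


def convert_units_to_ddd(
    uptake: pd.DataFrame,
    molecules: dict[str, MoleculeSpec],
    horizon: AnalysisHorizon,
) -> pd.DataFrame:
    """Exact linear conversion of dispensed units to DDDs.

    Returns a frame indexed by (code, year) over all horizon years with
    columns ``ddd_originator`` / ``ddd_biosimilar``; years without uptake
    rows are zero.
    """
    idx = pd.MultiIndex.from_product(
        [sorted(molecules), horizon.years], names=["code", "year"]
    )
    out = pd.DataFrame(0.0, index=idx, columns=["ddd_originator", "ddd_biosimilar"])
    for _, row in uptake.iterrows():
        code = row["code"]
        if code not in molecules:
            raise ReferentialError(f"uptake references unknown molecule {code!r}")
        spec = molecules[code]
        pres = row.get("presentation_id", "") or ""
        if pres:
            if pres not in spec.ddd_per_unit:
                raise ReferentialError(
                    f"molecule {code}: no DDD factor for presentation {pres!r}"
                )
            factor = spec.ddd_per_unit[pres]
        else:
            if len(spec.ddd_per_unit) > 1:
                raise ReferentialError(
                    f"molecule {code}: presentation_id required, multiple factors exist"
                )
            factor = next(iter(spec.ddd_per_unit.values()))
        col = "ddd_" + row["product_class"]
        out.loc[(code, int(row["year"])), col] += float(row["units"]) * factor
    return out


def uptake_share(ddd_originator: float, ddd_biosimilar: float) -> float:
    """Biosimilar share of total DDDs; NaN when total volume is zero."""
    total = ddd_originator + ddd_biosimilar
    if total <= 0:
        return float("nan")
    return ddd_biosimilar / total


# --------------------------------------------------------------------------
# Prepared arrays: the numeric core shared by base case, scenarios and PSA


@dataclass
class PreparedMolecule:
    """Numeric arrays for one molecule over the horizon.

    prices: (n_years, 12, 2) actual-scenario EUR/DDD, NaN where a class is
        not yet priced; last axis ordered (originator, biosimilar).
    weights: (n_years, 12, 2) within-year spreading of annual volume;
        rows sum to 1 over the priced months of each class.
    ddd: (n_years, 2); discount: (n_years, 2); frozen_price: scalar.
    """

    code: str
    ddd: np.ndarray
    prices: np.ndarray
    weights: np.ndarray
    discount: np.ndarray
    frozen_price: float


@dataclass
class PreparedMarket:
    horizon: AnalysisHorizon
    molecules: dict[str, PreparedMolecule]
    discount_series: dict[str, DiscountSeries]

    def copy(self) -> "PreparedMarket":
        return PreparedMarket(
            self.horizon,
            {
                c: PreparedMolecule(
                    m.code, m.ddd.copy(), m.prices.copy(), m.weights.copy(),
                    m.discount.copy(), m.frozen_price,
                )
                for c, m in self.molecules.items()
            },
            self.discount_series,
        )


def _month_weights(prices: np.ndarray, spreading: str) -> np.ndarray:
    """Spreading weights per (year, month, class) given price availability.

    A class's annual volume is carried only by months in which it is
    priced (a molecule entering mid-year contributes from its first
    priced month). Uniform spreading splits volume equally across those
    months; year-start puts it all on the first priced month.
    """
    n_years = prices.shape[0]
    weights = np.zeros_like(prices)
    priced = ~np.isnan(prices)
    for c in range(2):
        for y in range(n_years):
            idx = np.flatnonzero(priced[y, :, c])
            if idx.size == 0:
                continue
            if spreading == "uniform":
                weights[y, idx, c] = 1.0 / idx.size
            else:  # year_start
                weights[y, idx[0], c] = 1.0
    return weights


def prepare_market(inputs: MarketInputs, config: EngineConfig | None = None) -> PreparedMarket:
    """Run pricing and discount estimation; freeze everything into arrays."""
    config = config or EngineConfig()
    horizon = inputs.horizon
    n_years = horizon.n_years
    ddd_table = convert_units_to_ddd(inputs.uptake, inputs.molecules, horizon)

    prepared: dict[str, PreparedMolecule] = {}
    dseries: dict[str, DiscountSeries] = {}
    for code, spec in inputs.molecules.items():
        efp = inputs.prices[inputs.prices["code"] == code]
        rpos = inputs.rpo_events[inputs.rpo_events["code"] == code]
        timeline = build_price_timeline(spec, efp, rpos, horizon, config.pricing)
        frozen = counterfactual_price_timeline(spec, efp, horizon)

        prices = np.stack(
            [timeline[c].to_numpy().reshape(n_years, 12) for c in CLASSES], axis=-1
        )
        weights = _month_weights(prices, config.spreading)

        ds = assemble_discount_series(
            spec,
            inputs.tenders[inputs.tenders["code"] == code],
            inputs.discount_overrides[inputs.discount_overrides["code"] == code],
            timeline,
            horizon,
            spread_over_contract=config.spread_over_contract,
            regression_method=config.regression_method,
        )
        dseries[code] = ds
        discount = ds.values[[c.value for c in CLASSES]].to_numpy()
        if not config.discounts_enabled:
            discount = np.zeros_like(discount)

        ddd = ddd_table.loc[code][["ddd_originator", "ddd_biosimilar"]].to_numpy()
        prepared[code] = PreparedMolecule(
            code=code,
            ddd=ddd,
            prices=prices,
            weights=weights,
            discount=discount,
            frozen_price=float(frozen.iloc[0]),
        )
    return PreparedMarket(horizon, prepared, dseries)


def _annual_costs(pm: PreparedMolecule) -> tuple[np.ndarray, np.ndarray]:
    """(cost_without, cost_with) per year for one prepared molecule."""
    # effective annual price per class: spreading-weighted mean of monthly prices
    has_volume = pm.ddd > 0
    weighted = np.where(np.isnan(pm.prices), 0.0, pm.prices) * pm.weights
    eff_price = weighted.sum(axis=1)  # (n_years, 2)
    covered = pm.weights.sum(axis=1)  # 1 where the class is priced at all
    unpriced = has_volume & (covered < 1.0 - 1e-12)
    if unpriced.any():
        y = int(np.argwhere(unpriced)[0][0])
        raise UnpriceableError(
            f"molecule {pm.code}: consumption in an unpriced period "
            f"(year index {y})"
        )
    cost_with = (pm.ddd * eff_price * (1.0 - pm.discount)).sum(axis=1)
    cost_without = pm.ddd.sum(axis=1) * pm.frozen_price
    return cost_without, cost_with


def cost_actual_scenario(pm: PreparedMolecule) -> np.ndarray:
    """Annual actual-scenario cost (EUR) for one prepared molecule."""
    return _annual_costs(pm)[1]


def cost_counterfactual_scenario(pm: PreparedMolecule) -> np.ndarray:
    """Annual counterfactual cost: conserved total demand × frozen price."""
    return _annual_costs(pm)[0]


# --------------------------------------------------------------------------
# Results


@dataclass
class BIAResult:
    """Per-molecule-per-year costs of both scenarios and their difference.

    ``table`` is indexed by (code, year) with columns ``cost_without``,
    ``cost_with`` and ``savings`` (EUR; reports rescale to EUR million).
    """

    table: pd.DataFrame

    @classmethod
    def from_costs(cls, rows: list[tuple[str, int, float, float]]) -> "BIAResult":
        df = pd.DataFrame(rows, columns=["code", "year", "cost_without", "cost_with"])
        df["savings"] = df["cost_without"] - df["cost_with"]
        return cls(df.set_index(["code", "year"]).sort_index())

    def per_molecule(self) -> pd.DataFrame:
        return self.table.groupby(level="code").sum()

    def per_year(self) -> pd.DataFrame:
        return self.table.groupby(level="year").sum()

    def totals(self) -> dict[str, float]:
        t = self.table.sum()
        return {
            "cost_without": float(t["cost_without"]),
            "cost_with": float(t["cost_with"]),
            "savings": float(t["savings"]),
        }

    def total_savings(self) -> float:
        return self.totals()["savings"]

    def mean_annual_savings_per_marketed_molecule(
        self, launch_years: dict[str, int] | None = None
    ) -> pd.Series:
        """Per-year mean savings over molecules whose biosimilar is marketed.

        With ``launch_years`` (code → first biosimilar year) a molecule
        counts from its launch year on; without it, molecule-years with
        nonzero savings serve as a proxy for effective marketing.
        """
        tab = self.table.reset_index()
        if launch_years is not None:
            marketed = tab.apply(
                lambda r: r["year"] >= launch_years.get(r["code"], np.inf), axis=1
            )
        else:
            marketed = tab["savings"] != 0
        per_year = tab[marketed].groupby("year")["savings"]
        return per_year.sum() / per_year.count()


def compute_bia(
    inputs: MarketInputs | PreparedMarket, config: EngineConfig | None = None
) -> BIAResult:
    """Full budget-impact computation: savings = counterfactual − actual."""
    prepared = (
        inputs if isinstance(inputs, PreparedMarket) else prepare_market(inputs, config)
    )
    rows: list[tuple[str, int, float, float]] = []
    for code, pm in prepared.molecules.items():
        without, with_ = _annual_costs(pm)
        for y, cw, ca in zip(prepared.horizon.years, without, with_):
            rows.append((code, int(y), float(cw), float(ca)))
    return BIAResult.from_costs(rows)


def savings_share(result: BIAResult, molecule_subset) -> float:
    """Percent of total savings contributed by a subset of molecules."""
    total = result.total_savings()
    if total == 0:
        raise ZeroDivisionError("total savings is zero; share undefined")
    per_mol = result.per_molecule()["savings"]
    subset = [c for c in molecule_subset]
    return 100.0 * float(per_mol.reindex(subset).fillna(0.0).sum()) / total


def savings_vs_total_spend(
    result: BIAResult,
    spend_by_year: dict[int, float],
    years: list[int] | None = None,
) -> pd.Series:
    """Annual savings as a percent of an external total-spend series (EUR).

    ``years`` defaults to every year of the result; a requested year with
    no spend figure is an error (the external series is an input, never
    interpolated).
    """
    per_year = result.per_year()["savings"]
    if years is None:
        years = list(per_year.index)
    out = {}
    for year in years:
        if year not in spend_by_year:
            raise KeyError(f"no total-spend figure for year {year}")
        spend = spend_by_year[year]
        if not spend > 0:
            raise ValueError(f"total spend for {year} must be positive")
        out[year] = 100.0 * float(per_year.get(year, 0.0)) / spend
    return pd.Series(out, name="savings_pct_of_spend")
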