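"""Commercial discount estimation from hospital tender awards.

Hospitals buy off-patent biologicals through public tenders at bid prices
below the regulated list price (EFP, or RP once a reference-price order
applies); the gap is the commercial discount. For each molecule, class
and year the discount is the volume-weighted shortfall of purchase prices
against the list price prevailing at each award month. Years without
observations are backfilled by a linear regression anchored at zero
discount the year before the first biosimilar launch — competition starts
the discount clock. Retail-channel molecules carry no discount at all.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DiscountEstimationError, UnpriceableError
from .market_model import AnalysisHorizon, Channel, MoleculeSpec, ProductClass

__all__ = [
    "Provenance",
    "DiscountSeries",
    "annual_weighted_discount",
    "backfill_discounts_regression",
    "assemble_discount_series",
    "discount_tier",
]

logger = logging.getLogger(__name__)

DISCOUNT_CAP = 0.95  # regression extrapolations never exceed this fraction


class Provenance(str, enum.Enum):
    observed = "observed"
    regressed = "regressed"
    zero_by_channel = "zero_by_channel"


@dataclass
class DiscountSeries:
    """Per-year discount fractions for one molecule, by product class.

    ``values`` and ``provenance`` are frames indexed by year with one
    column per product class; fractions lie in [0, 0.95].
    """

    molecule_code: str
    values: pd.DataFrame
    provenance: pd.DataFrame

    def fraction(self, year: int, pclass: ProductClass) -> float:
        return float(self.values.loc[year, pclass.value])


def _attributed_volume(row: pd.Series, year: int, spread_over_contract: bool) -> float:
    """Units of one award attributed to ``year``.

    With contract spreading the award's volume is apportioned uniformly
    over the months its contract covers; otherwise the whole volume lands
    in the award year.
    """
    if not spread_over_contract:
        return float(row["volume_units"]) if row["award_date"].year == year else 0.0
    start: pd.Period = row["contract_start"]
    end: pd.Period = row["contract_end"]
    total_months = (end - start).n + 1
    y_start = max(start, pd.Period(f"{year}-01", freq="M"))
    y_end = min(end, pd.Period(f"{year}-12", freq="M"))
    overlap = (y_end - y_start).n + 1 if y_start <= y_end else 0
    return float(row["volume_units"]) * overlap / total_months


def annual_weighted_discount(
    tenders: pd.DataFrame,
    list_price: dict[ProductClass, pd.Series],
    ddd_factor: float,
    year: int,
    spread_over_contract: bool = True,
) -> dict[ProductClass, float | None]:
    """Volume-weighted commercial discount for one molecule and year.

    For each class, ``1 − Σ v·p / Σ v·L`` over awards attributed to the
    year, where ``p`` is the purchase price per unit and ``L`` the list
    price per unit (EUR/DDD timeline × DDD-per-unit factor) at the award
    month. Returns None for a class with no attributable awards — absence
    of observation, not a zero discount. Negative aggregates (bids above
    list) clamp to zero with a warning.
    """
    out: dict[ProductClass, float | None] = {}
    for pclass in ProductClass:
        sub = tenders[tenders["product_class"] == pclass.value]
        num = 0.0  # Σ volume × purchase price
        den = 0.0  # Σ volume × list price
        for _, row in sub.iterrows():
            vol = _attributed_volume(row, year, spread_over_contract)
            if vol <= 0:
                continue
            award_month = pd.Period(row["award_date"], freq="M")
            series = list_price[pclass]
            if award_month not in series.index or np.isnan(series.loc[award_month]):
                raise UnpriceableError(
                    f"tender {row['tender_id']}: no {pclass.value} list price at "
                    f"award month {award_month}"
                )
            lp_unit = float(series.loc[award_month]) * ddd_factor
            num += vol * float(row["purchase_price_per_unit"])
            den += vol * lp_unit
        if den == 0.0:
            out[pclass] = None
            continue
        d = 1.0 - num / den
        if d < 0:
            logger.warning(
                "negative weighted discount %.4f clamped to 0 (year %d, %s)",
                d, year, pclass.value,
            )
            d = 0.0
        out[pclass] = d
    return out


def backfill_discounts_regression(
    observed: dict[int, float],
    anchor_year: int,
    years: np.ndarray | list[int],
    method: str = "constrained",
) -> tuple[dict[int, float], float]:
    """Fill unobserved years with a line anchored at (anchor_year, 0).

    The base method fits d(t) = β·(t − anchor) by least squares
    constrained through the anchor: β = Σ tᵢdᵢ / Σ tᵢ². The alternative
    treats the anchor as a pseudo-observation in an ordinary fit through
    the origin-shifted coordinates. Predictions are clamped to
    [0, 0.95]; observed years keep their observed values.

    Returns (year → discount, fitted slope).
    """
    if not observed:
        raise DiscountEstimationError(
            "no discount observations to regress from; mark the molecule "
            "zero_by_channel or supply an explicit series"
        )
    t = np.array([y - anchor_year for y in observed], dtype=float)
    d = np.array(list(observed.values()), dtype=float)
    if method == "constrained":
        beta = float(np.sum(t * d) / np.sum(t * t))
    elif method == "ols_pseudo":
        # anchor enters as a data point; intercept-free OLS on shifted years
        t2 = np.append(t, 0.0)
        d2 = np.append(d, 0.0)
        beta = float(np.sum(t2 * d2) / np.sum(t2 * t2))
    else:
        raise ValueError(f"unknown regression method {method!r}")

    series: dict[int, float] = {}
    for y in years:
        y = int(y)
        if y in observed:
            series[y] = float(observed[y])
        else:
            series[y] = float(np.clip(beta * (y - anchor_year), 0.0, DISCOUNT_CAP))
    return series, beta


def assemble_discount_series(
    molecule: MoleculeSpec,
    tenders: pd.DataFrame,
    overrides: pd.DataFrame,
    list_price: dict[ProductClass, pd.Series],
    horizon: AnalysisHorizon,
    spread_over_contract: bool = True,
    regression_method: str = "constrained",
) -> DiscountSeries:
    """Full per-year discount series for one molecule.

    Retail molecules get an all-zero series (no tender channel). Hospital
    molecules combine tender-derived weighted discounts, direct
    observations from ``overrides`` (which win over tender-derived values
    for the same year), and regression backfill anchored the year before
    biosimilar launch for the remaining years.
    """
    years = horizon.years
    cols = [c.value for c in ProductClass]
    values = pd.DataFrame(0.0, index=years, columns=cols)
    prov = pd.DataFrame(Provenance.regressed.value, index=years, columns=cols)

    if molecule.channel is Channel.retail or not molecule.discount_applicable:
        prov.loc[:, :] = Provenance.zero_by_channel.value
        return DiscountSeries(molecule.code, values, prov)

    anchor = molecule.launch_year - 1
    observed_by_class: dict[ProductClass, dict[int, float]] = {}
    for pclass in ProductClass:
        observed: dict[int, float] = {}
        for year in years:
            w = annual_weighted_discount(
                tenders, list_price, molecule.mean_ddd_factor(), int(year),
                spread_over_contract,
            )[pclass]
            if w is not None:
                observed[int(year)] = w
        ov = overrides[overrides["product_class"] == pclass.value]
        for _, r in ov.iterrows():
            observed[int(r["year"])] = float(r["discount_fraction"])
        observed_by_class[pclass] = observed
    if not any(observed_by_class.values()):
        raise DiscountEstimationError(
            f"molecule {molecule.code}: hospital channel but no tenders and no "
            "discount observations in either product class"
        )
    for pclass in ProductClass:
        observed = observed_by_class[pclass]
        if not observed:
            # a class never tendered (e.g. a biosimilar that never sold)
            # carries a zero discount; it has no volume to discount anyway
            logger.warning(
                "molecule %s/%s: no discount observations for this class; "
                "using a zero series", molecule.code, pclass.value,
            )
            continue
        series, beta = backfill_discounts_regression(
            observed, anchor, years, method=regression_method
        )
        n_regressed = 0
        for year in years:
            y = int(year)
            values.loc[y, pclass.value] = series[y]
            if y in observed:
                prov.loc[y, pclass.value] = Provenance.observed.value
            else:
                n_regressed += 1
        if n_regressed:
            logger.info(
                "discount backfill: molecule %s/%s, %d year(s) regressed "
                "(slope %.4f/yr, anchor %d)",
                molecule.code, pclass.value, n_regressed, beta, anchor,
            )
    return DiscountSeries(molecule.code, values, prov)


def discount_tier(fraction: float) -> str:
    """Tier label for a discount fraction: '+' 0–25%, '++' 25–50%, '+++' >50%."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"discount fraction {fraction} outside [0, 1]")
    if fraction > 0.50:
        return "+++"
    if fraction >= 0.25:
        return "++"
    return "+"
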