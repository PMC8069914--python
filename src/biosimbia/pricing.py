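"""Monthly list-price timelines under a reference-price system.

The list price a payer faces at any month is the ex-factory price (EFP)
in force, replaced by the reference price (RP) once a reference-price
order (RPO) takes effect — both the originator and the biosimilar share
the RP from that month on. An RPO published before the 15th of a month
takes effect that same month, otherwise the following month. When a
biosimilar's own price between its launch and the first RPO is unknown,
it is imputed as the first RP plus a 10% markup, the pattern observed on
molecules with complete price histories.

Prices are carried in EUR per defined daily dose (DDD) and are piecewise
constant between events (forward-fill convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UnpriceableError
from .market_model import AnalysisHorizon, MoleculeSpec, ProductClass

__all__ = [
    "PricingConfig",
    "rpo_effective_month",
    "impute_pre_rpo_biosimilar_price",
    "build_price_timeline",
    "counterfactual_price_timeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PricingConfig:
    """Knobs of the price-timeline rules.

    day_cutoff: first day-of-month on which an RPO defers to the next
        month (the base rule reads "prior to the 15th" strictly, so 15).
    rpo_month_shift: shifts every RPO effective month, for the ±1-month
        one-way sensitivity analysis.
    pre_rpo_markup: relative markup over the first RP used to impute an
        unobserved biosimilar price before the first RPO (base 10%).
    pre_rpo_price_factor: extra multiplier on the imputed price, for the
        ±50% one-way sensitivity analysis.
    impute_pre_rpo: disable to make an unpriced pre-RPO gap a hard error.
    """

    day_cutoff: int = 15
    rpo_month_shift: int = 0
    pre_rpo_markup: float = 0.10
    pre_rpo_price_factor: float = 1.0
    impute_pre_rpo: bool = True


def rpo_effective_month(
    publication_date, day_cutoff: int = 15, month_shift: int = 0
) -> pd.Period:
    """Month from which a reference-price order affects prices.

    Publication strictly before the cutoff day applies in the same month,
    otherwise the next month; December rolls into January.
    """
    ts = pd.Timestamp(publication_date)
    month = pd.Period(ts, freq="M")
    if ts.day >= day_cutoff:
        month += 1
    return month + month_shift


def impute_pre_rpo_biosimilar_price(rp_per_ddd: float, markup: float = 0.10) -> float:
    """Imputed biosimilar list price before its first RPO: RP × (1 + markup)."""
    if not rp_per_ddd > 0:
        raise ValueError(f"reference price must be positive, got {rp_per_ddd}")
    return rp_per_ddd * (1.0 + markup)


def _step_series(months: pd.PeriodIndex, events: list[tuple[pd.Period, float]]) -> pd.Series:
    """Piecewise-constant series on the month grid from (month, value) events."""
    s = pd.Series(np.nan, index=months, dtype=float)
    for m, v in sorted(events, key=lambda e: e[0]):
        i = months.searchsorted(m)
        if m < months[0]:
            i = 0
        if i < len(months):
            s.iloc[i:] = v
        elif m <= months[-1]:
            s.iloc[-1:] = v
    return s


def build_price_timeline(
    molecule: MoleculeSpec,
    efp: pd.DataFrame,
    rpos: pd.DataFrame,
    horizon: AnalysisHorizon,
    config: PricingConfig | None = None,
) -> dict[ProductClass, pd.Series]:
    """Actual-scenario monthly list price per DDD for each product class.

    ``efp`` has columns (product_class, effective_month, efp_per_ddd) for
    this molecule; ``rpos`` has (publication_date, rp_per_ddd). Months
    before a class is priced (biosimilar before launch, originator before
    its first record) are NaN. RP replaces the EFP from its effective
    month unless the RP lies above the prevailing EFP, in which case the
    cap is a no-op and a warning is logged.
    """
    config = config or PricingConfig()
    months = horizon.months

    rp_events = [
        (
            rpo_effective_month(r["publication_date"], config.day_cutoff, config.rpo_month_shift),
            float(r["rp_per_ddd"]),
        )
        for _, r in rpos.iterrows()
    ]
    rp_series = _step_series(months, rp_events)
    first_rp_eff: pd.Period | None = None
    first_rp: float | None = None
    if rp_events:
        first_rp_eff, first_rp = min(rp_events, key=lambda e: e[0])

    out: dict[ProductClass, pd.Series] = {}
    for pclass in ProductClass:
        sub = efp[efp["product_class"] == pclass.value]
        efp_series = _step_series(
            months,
            [(r["effective_month"], float(r["efp_per_ddd"])) for _, r in sub.iterrows()],
        )
        price = efp_series.copy()
        has_rp = rp_series.notna()
        replace = has_rp & (efp_series.isna() | (rp_series <= efp_series))
        price[replace] = rp_series[replace]
        noop = has_rp & efp_series.notna() & (rp_series > efp_series)
        if noop.any():
            logger.warning(
                "RP above prevailing EFP for %s/%s in %d month(s); cap is a no-op",
                molecule.code, pclass.value, int(noop.sum()),
            )

        if pclass is ProductClass.biosimilar:
            launch = molecule.first_biosimilar_year_month
            pre_launch = months < launch
            price[pre_launch] = np.nan
            gap = (months >= launch) & price.isna().to_numpy()
            if first_rp_eff is not None:
                gap &= months < first_rp_eff
            if gap.any():
                if first_rp is None:
                    # no RP to impute from; leave NaN, costing errors if volume appears
                    logger.warning(
                        "biosimilar %s has unpriced months and no RPO; leaving unpriced",
                        molecule.code,
                    )
                elif not config.impute_pre_rpo:
                    raise UnpriceableError(
                        f"molecule {molecule.code}: biosimilar unpriced between launch "
                        "and first RPO and imputation is disabled"
                    )
                else:
                    imputed = (
                        impute_pre_rpo_biosimilar_price(first_rp, config.pre_rpo_markup)
                        * config.pre_rpo_price_factor
                    )
                    price[gap] = imputed
                    logger.info(
                        "pre-RPO imputation applied: molecule %s, %d month(s) at %.4f EUR/DDD",
                        molecule.code, int(gap.sum()), imputed,
                    )
        out[pclass] = price
    return out


def counterfactual_price_timeline(
    molecule: MoleculeSpec,
    efp: pd.DataFrame,
    horizon: AnalysisHorizon,
) -> pd.Series:
    """Frozen originator price for the no-biosimilar counterfactual.

    The originator list price in force at the month before the first
    biosimilar launch (or at horizon start, for molecules whose biosimilar
    predates the horizon) is held flat over every month of the horizon;
    no reference prices and no discounts apply in this scenario.
    """
    months = horizon.months
    if len(months) == 0:
        return pd.Series(dtype=float)
    launch = molecule.first_biosimilar_year_month
    freeze_month = max(launch - 1, months[0])

    sub = efp[efp["product_class"] == ProductClass.originator.value]
    sub = sub.sort_values("effective_month")
    if sub.empty:
        raise UnpriceableError(
            f"molecule {molecule.code}: no originator EFP record to freeze the "
            "counterfactual price"
        )
    in_force = sub[sub["effective_month"] <= freeze_month]
    if len(in_force):
        frozen = float(in_force.iloc[-1]["efp_per_ddd"])
    else:
        # records begin after the freeze month: use the earliest available price
        frozen = float(sub.iloc[0]["efp_per_ddd"])
        logger.info(
            "counterfactual freeze for %s uses earliest available originator price "
            "(records start %s, freeze month %s)",
            molecule.code, sub.iloc[0]["effective_month"], freeze_month,
        )
    return pd.Series(frozen, index=months, dtype=float)
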