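"""Deterministic scenarios, one-way analyses and Monte Carlo PSA.

Three layers of robustness checking sit on top of the costing engine:

* scenario analysis — structural switches (drop all commercial
  discounts; attribute tender volumes to the award year only);
* one-way analysis — single parameters moved to their bounds (imputed
  pre-RPO biosimilar price ±50%, reference-price effective month
  ±1 month, epoetin biosimilar share 2011–2015 ±20%);
* probabilistic sensitivity analysis — 1000 Monte Carlo draws varying
  every per-molecule-year price, discount and biosimilar share from a
  normal distribution centred on the base case, truncated by rejection
  to the valid range (prices > 0, shares in [0, 1], discounts in
  [0, 0.95]), summarised by the mean and a percentile interval.

Reproducibility: one root seed; each simulation draws from its own
substream spawned from the root seed sequence, so results do not depend
on iteration order.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (
    BIAResult,
    EngineConfig,
    PreparedMarket,
    compute_bia,
    prepare_market,
)
from .errors import ConfigError
from .market_model import MarketInputs

__all__ = [
    "ScenarioVariant",
    "OneWayParameter",
    "PSAConfig",
    "PSAResult",
    "run_scenario",
    "run_one_way",
    "tornado_table",
    "run_psa",
]

logger = logging.getLogger(__name__)


class ScenarioVariant(str, enum.Enum):
    base = "base"
    no_discounts = "no_discounts"
    no_volume_weighting = "no_volume_weighting"


class OneWayParameter(str, enum.Enum):
    pre_rpo_price = "pre_rpo_price"
    rpo_application_month = "rpo_application_month"
    epoetin_share = "epoetin_share"


def run_scenario(
    variant: ScenarioVariant,
    inputs: MarketInputs,
    config: EngineConfig | None = None,
) -> BIAResult:
    """Run the pipeline under a deterministic scenario variant.

    ``no_discounts`` zeroes every commercial discount while keeping the
    reference-price erosion (the minimum-savings scenario);
    ``no_volume_weighting`` attributes each tender's volume entirely to
    its award year instead of spreading it over the contract.
    """
    config = config or EngineConfig()
    variant = ScenarioVariant(variant)
    if variant is ScenarioVariant.no_discounts:
        config = dataclasses.replace(config, discounts_enabled=False)
    elif variant is ScenarioVariant.no_volume_weighting:
        config = dataclasses.replace(config, spread_over_contract=False)
    return compute_bia(inputs, config)


def _scale_biosimilar_share(
    prepared: PreparedMarket, code: str, years: list[int], factor: float
) -> PreparedMarket:
    """Rescale the biosimilar DDD share, conserving total demand."""
    out = prepared.copy()
    if code not in out.molecules:
        logger.warning("share variation: molecule %s not in market; no-op", code)
        return out
    pm = out.molecules[code]
    year_index = {int(y): i for i, y in enumerate(prepared.horizon.years)}
    for y in years:
        if int(y) not in year_index:
            continue
        i = year_index[int(y)]
        total = pm.ddd[i].sum()
        if total <= 0:
            continue
        share = pm.ddd[i, 1] / total
        new_share = float(np.clip(share * factor, 0.0, 1.0))
        pm.ddd[i, 1] = new_share * total
        pm.ddd[i, 0] = total - pm.ddd[i, 1]
    return out


def run_one_way(
    parameter: OneWayParameter,
    inputs: MarketInputs,
    config: EngineConfig | None = None,
    *,
    share_molecule: str = "EPO",
    share_years: tuple[int, ...] = (2011, 2012, 2013, 2014, 2015),
    price_delta: float = 0.50,
    month_delta: int = 1,
    share_delta: float = 0.20,
) -> tuple[BIAResult, BIAResult]:
    """(low, high) results with one parameter moved to its bounds.

    * pre_rpo_price: imputed pre-RPO biosimilar price × (1∓price_delta);
    * rpo_application_month: every RPO effective month shifted ∓1;
    * epoetin_share: biosimilar share of the named molecule in the given
      years × (1∓share_delta), total demand conserved.

    A variation with nothing to act on (no imputed months, no RPOs, no
    such molecule) returns the base case twice with a warning.
    """
    config = config or EngineConfig()
    parameter = OneWayParameter(parameter)

    if parameter is OneWayParameter.pre_rpo_price:
        results = []
        for f in (1.0 - price_delta, 1.0 + price_delta):
            pricing = dataclasses.replace(config.pricing, pre_rpo_price_factor=f)
            results.append(compute_bia(inputs, dataclasses.replace(config, pricing=pricing)))
        return results[0], results[1]

    if parameter is OneWayParameter.rpo_application_month:
        if inputs.rpo_events.empty:
            logger.warning("one-way RPO month shift: no RPO events; returning base case")
            base = compute_bia(inputs, config)
            return base, base
        results = []
        for shift in (-month_delta, +month_delta):
            pricing = dataclasses.replace(config.pricing, rpo_month_shift=shift)
            results.append(compute_bia(inputs, dataclasses.replace(config, pricing=pricing)))
        return results[0], results[1]

    # epoetin_share
    prepared = prepare_market(inputs, config)
    if share_molecule not in prepared.molecules:
        logger.warning(
            "one-way share variation: molecule %s absent; returning base case",
            share_molecule,
        )
        base = compute_bia(prepared)
        return base, base
    low = compute_bia(
        _scale_biosimilar_share(prepared, share_molecule, list(share_years), 1.0 - share_delta)
    )
    high = compute_bia(
        _scale_biosimilar_share(prepared, share_molecule, list(share_years), 1.0 + share_delta)
    )
    return low, high


def tornado_table(
    one_way_results: dict[str, tuple[BIAResult, BIAResult]],
    base_total: float | None = None,
) -> pd.DataFrame:
    """Total-savings ranges per variation, widest first (tornado layout)."""
    rows = []
    for name, (low, high) in one_way_results.items():
        lo, hi = low.total_savings(), high.total_savings()
        rows.append(
            {
                "parameter": name,
                "low_total_savings": lo,
                "high_total_savings": hi,
                "range": abs(hi - lo),
            }
        )
    df = pd.DataFrame(rows).sort_values("range", ascending=False).reset_index(drop=True)
    if base_total is not None:
        df["base_total_savings"] = base_total
    return df


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo configuration.

    SDs are relative (fraction of the base value) per parameter family;
    they are a modelling convention, configurable per run. Truncation
    keeps draws in the valid range by rejection.
    """

    seed: int
    n_simulations: int = 1000
    sd_price: float = 0.10
    sd_discount: float = 0.10
    sd_share: float = 0.10
    discount_cap: float = 0.95
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ConfigError("n_simulations must be >= 1")
        for name in ("sd_price", "sd_discount", "sd_share"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError("ci_level must be in (0, 1)")
        if not (0.0 < self.discount_cap <= 1.0):
            raise ConfigError("discount_cap must be in (0, 1]")


@dataclass
class PSAResult:
    """Summary and raw draws of a probabilistic sensitivity analysis.

    ``draws`` holds one row per (simulation, molecule) with the
    molecule's total DDD volume and cumulative savings — the material of
    a savings-vs-consumption scatter plot. ``summary`` has one row per
    molecule plus TOTAL with base case, mean and percentile CI bounds.
    """

    summary: pd.DataFrame
    draws: pd.DataFrame
    config: PSAConfig


def _truncated_normal(
    rng: np.random.Generator,
    sd: float,
    lower_mult: np.ndarray | float,
    upper_mult: np.ndarray | float,
    size: int,
    max_tries: int = 1000,
) -> np.ndarray:
    """Multipliers ~ N(1, sd) rejected into [lower_mult, upper_mult]."""
    if sd == 0.0:
        return np.ones(size)
    out = np.ones(size)
    pending = np.ones(size, dtype=bool)
    lo = np.broadcast_to(np.asarray(lower_mult, dtype=float), (size,))
    hi = np.broadcast_to(np.asarray(upper_mult, dtype=float), (size,))
    for _ in range(max_tries):
        draw = rng.normal(1.0, sd, size=int(pending.sum()))
        idx = np.flatnonzero(pending)
        out[idx] = draw
        ok = (out >= lo) & (out <= hi)
        pending = ~ok
        if not pending.any():
            return out
    raise ConfigError("truncated-normal rejection failed; bounds too tight for the SD")


def run_psa(
    inputs: MarketInputs | PreparedMarket,
    psa: PSAConfig,
    config: EngineConfig | None = None,
) -> PSAResult:
    """Monte Carlo PSA over prices, discounts and biosimilar shares.

    Every (molecule, year) gets an independent multiplier per parameter
    family, drawn from a truncated normal centred at 1. The price
    multiplier scales both scenarios' prices for that molecule-year; the
    discount multiplier scales both classes' discount fractions (capped
    at 0.95); the share multiplier rescales the biosimilar share with
    total demand conserved. Savings are recomputed per draw with the
    same costing rules as the base case.
    """
    prepared = (
        inputs if isinstance(inputs, PreparedMarket) else prepare_market(inputs, config)
    )
    codes = list(prepared.molecules)
    n_years = prepared.horizon.n_years

    # base-case per-molecule building blocks
    eff_price: dict[str, np.ndarray] = {}
    total_ddd: dict[str, np.ndarray] = {}
    base_share: dict[str, np.ndarray] = {}
    for code, pm in prepared.molecules.items():
        eff_price[code] = np.nansum(
            np.where(np.isnan(pm.prices), 0.0, pm.prices) * pm.weights, axis=1
        )
        tot = pm.ddd.sum(axis=1)
        total_ddd[code] = tot
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(tot > 0, pm.ddd[:, 1] / np.where(tot > 0, tot, 1.0), 0.0)
        base_share[code] = share

    root = np.random.SeedSequence(psa.seed)
    children = root.spawn(psa.n_simulations)

    draw_rows = []
    for sim, child in enumerate(children):
        rng = np.random.default_rng(child)
        for code in codes:
            pm = prepared.molecules[code]
            d = pm.discount  # (n_years, 2)
            share = base_share[code]
            tot = total_ddd[code]

            m_price = _truncated_normal(rng, psa.sd_price, 1e-12, np.inf, n_years)
            dmax = d.max(axis=1)
            upper_d = np.where(dmax > 0, psa.discount_cap / np.where(dmax > 0, dmax, 1.0), np.inf)
            m_disc = _truncated_normal(rng, psa.sd_discount, 0.0, upper_d, n_years)
            upper_s = np.where(share > 0, 1.0 / np.where(share > 0, share, 1.0), np.inf)
            m_share = _truncated_normal(rng, psa.sd_share, 0.0, upper_s, n_years)

            new_share = share * m_share
            ddd_b = new_share * tot
            ddd = np.stack([tot - ddd_b, ddd_b], axis=-1)
            disc = d * m_disc[:, None]
            prices = eff_price[code] * m_price[:, None]

            cost_with = (ddd * prices * (1.0 - disc)).sum(axis=1)
            cost_without = tot * pm.frozen_price * m_price
            draw_rows.append(
                (sim, code, float(tot.sum()), float((cost_without - cost_with).sum()))
            )

    draws = pd.DataFrame(draw_rows, columns=["sim", "code", "total_ddd", "savings"])

    base = compute_bia(prepared).per_molecule()["savings"]
    alpha = (1.0 - psa.ci_level) / 2.0
    rows = []
    per_mol = draws.pivot(index="sim", columns="code", values="savings")
    for code in codes:
        s = per_mol[code].to_numpy()
        rows.append(
            {
                "molecule": code,
                "base_case": float(base.get(code, 0.0)),
                "mean": float(s.mean()),
                "ci_low": float(np.percentile(s, 100 * alpha)),
                "ci_high": float(np.percentile(s, 100 * (1 - alpha))),
            }
        )
    tot_draws = per_mol.sum(axis=1).to_numpy()
    rows.append(
        {
            "molecule": "TOTAL",
            "base_case": float(base.sum()),
            "mean": float(tot_draws.mean()),
            "ci_low": float(np.percentile(tot_draws, 100 * alpha)),
            "ci_high": float(np.percentile(tot_draws, 100 * (1 - alpha))),
        }
    )
    summary = pd.DataFrame(rows).set_index("molecule")
    return PSAResult(summary=summary, draws=draws, config=psa)
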