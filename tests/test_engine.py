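"""Two-scenario costing: conversions, costs, aggregation, invariants."""

import numpy as np
import pandas as pd
import pytest

from biosimbia import (
    AnalysisHorizon,
    EngineConfig,
    compute_bia,
    convert_units_to_ddd,
    fixture_from_table1,
    generate_market,
    molecule_summary,
    prepare_market,
    savings_share,
    savings_vs_total_spend,
    uptake_share,
)
from biosimbia.engine import PreparedMolecule, cost_actual_scenario, cost_counterfactual_scenario
from biosimbia.errors import ReferentialError, UnpriceableError
from biosimbia.synthetic import SyntheticMarketConfig

from conftest import hospital_molecule, make_inputs


def _uptake(rows):
    return pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4] if len(r) > 4 else "") for r in rows],
        columns=["code", "year", "product_class", "units", "presentation_id"],
    )


class TestDDDConversion:
    horizon = AnalysisHorizon(2018, 2018)

    def test_linear_conversion(self):
        mols = {"AAA": hospital_molecule(factor=0.5, launch="2018-01")}
        ddd = convert_units_to_ddd(
            _uptake([("AAA", 2018, "originator", 100.0, "P1")]), mols, self.horizon
        )
        assert ddd.loc[("AAA", 2018), "ddd_originator"] == pytest.approx(50.0)
        assert ddd.loc[("AAA", 2018), "ddd_biosimilar"] == 0.0

    def test_multiple_presentations_sum(self):
        mol = hospital_molecule(launch="2018-01")
        mol = type(mol)(
            code="AAA", name="a", channel=mol.channel,
            first_biosimilar_year_month=mol.first_biosimilar_year_month,
            ddd_per_unit={"P1": 1.0, "P2": 0.25}, discount_applicable=True,
        )
        ddd = convert_units_to_ddd(
            _uptake(
                [("AAA", 2018, "originator", 10.0, "P1"),
                 ("AAA", 2018, "originator", 20.0, "P2")]
            ),
            {"AAA": mol}, self.horizon,
        )
        assert ddd.loc[("AAA", 2018), "ddd_originator"] == pytest.approx(15.0)

    def test_missing_factor_names_the_presentation(self):
        mols = {"AAA": hospital_molecule(launch="2018-01")}
        with pytest.raises(ReferentialError, match="P9"):
            convert_units_to_ddd(
                _uptake([("AAA", 2018, "originator", 10.0, "P9")]), mols, self.horizon
            )


class TestUptakeShare:
    @pytest.mark.parametrize(
        ("orig", "bio", "share"), [(60.0, 40.0, 0.40), (5.0, 0.0, 0.0), (0.0, 5.0, 1.0)]
    )
    def test_share_definition(self, orig, bio, share):
        assert uptake_share(orig, bio) == pytest.approx(share)

    def test_zero_total_volume_is_undefined(self):
        assert np.isnan(uptake_share(0.0, 0.0))


def _prepared(ddd, prices, discount, frozen):
    prices = np.asarray(prices, dtype=float)
    weights = np.zeros_like(prices)
    priced = ~np.isnan(prices)
    for c in range(2):
        for y in range(prices.shape[0]):
            idx = np.flatnonzero(priced[y, :, c])
            if idx.size:
                weights[y, idx, c] = 1.0 / idx.size
    return PreparedMolecule(
        code="AAA", ddd=np.asarray(ddd, dtype=float), prices=prices,
        weights=weights, discount=np.asarray(discount, dtype=float),
        frozen_price=frozen,
    )


class TestScenarioCosts:
    def test_flat_price_with_discount(self):
        # 120 DDD at 10 EUR/DDD with 20% discount -> 960
        pm = _prepared([[120.0, 0.0]], np.full((1, 12, 2), 10.0), [[0.2, 0.2]], 10.0)
        assert cost_actual_scenario(pm)[0] == pytest.approx(960.0)

    def test_zero_volume_zero_cost(self):
        pm = _prepared([[0.0, 0.0]], np.full((1, 12, 2), 10.0), [[0.0, 0.0]], 10.0)
        assert cost_actual_scenario(pm)[0] == 0.0
        assert cost_counterfactual_scenario(pm)[0] == 0.0

    def test_midyear_price_drop_prorated(self):
        # price 10 for 6 months then 8: 6*10*10 + 6*10*8 = 1080
        prices = np.full((1, 12, 2), 10.0)
        prices[0, 6:, :] = 8.0
        pm = _prepared([[120.0, 0.0]], prices, [[0.0, 0.0]], 10.0)
        assert cost_actual_scenario(pm)[0] == pytest.approx(1080.0)

    def test_counterfactual_conserves_total_demand(self):
        pm = _prepared([[60.0, 40.0]], np.full((1, 12, 2), 9.0), [[0.0, 0.0]], 10.0)
        assert cost_counterfactual_scenario(pm)[0] == pytest.approx(1000.0)

    def test_all_biosimilar_demand_reattributed_to_originator(self):
        pm = _prepared([[0.0, 100.0]], np.full((1, 12, 2), 9.0), [[0.0, 0.0]], 10.0)
        assert cost_counterfactual_scenario(pm)[0] == pytest.approx(1000.0)

    def test_volume_in_fully_unpriced_year_is_an_error(self):
        prices = np.full((1, 12, 2), np.nan)
        prices[0, :, 0] = 10.0  # originator priced, biosimilar not
        pm = _prepared([[50.0, 50.0]], prices, [[0.0, 0.0]], 10.0)
        with pytest.raises(UnpriceableError):
            cost_actual_scenario(pm)


class TestComputeBia:
    def test_toy_market_stagewise_hand_computation(self, toy_market):
        res = compute_bia(toy_market)
        sav = res.table["savings"]
        assert sav.loc[("TOY", 2010)] == pytest.approx(100.0)
        assert sav.loc[("TOY", 2011)] == pytest.approx(240.0)
        assert res.total_savings() == pytest.approx(340.0)

    def test_identical_scenarios_give_zero_savings(self):
        # no RP, no discounts, no biosimilar volume: the scenarios coincide
        mol = hospital_molecule("NUL", launch="2011-01")
        inputs = make_inputs(
            {"NUL": mol}, AnalysisHorizon(2010, 2011),
            uptake_rows=[("NUL", 2010, "originator", 50.0, "P1"),
                         ("NUL", 2011, "originator", 50.0, "P1")],
            price_rows=[("NUL", "originator", "2010-01", 10.0)],
            override_rows=[("NUL", "originator", 2011, 0.0),
                           ("NUL", "biosimilar", 2011, 0.0)],
        )
        res = compute_bia(inputs)
        assert np.allclose(res.table["savings"], 0.0)

    def test_aggregate_identities(self):
        market = generate_market(SyntheticMarketConfig(seed=5, n_molecules=4))
        res = compute_bia(market.inputs)
        tab = res.table
        assert np.allclose(tab["savings"], tab["cost_without"] - tab["cost_with"])
        per_mol = res.per_molecule()
        assert per_mol["savings"].sum() == pytest.approx(res.total_savings(), rel=1e-12)
        assert res.per_year()["savings"].sum() == pytest.approx(res.total_savings(), rel=1e-12)

    def test_demand_conservation_across_scenarios(self):
        market = generate_market(SyntheticMarketConfig(seed=6, n_molecules=4))
        prepared = prepare_market(market.inputs)
        res = compute_bia(prepared)
        for code, pm in prepared.molecules.items():
            total = pm.ddd.sum(axis=1)
            expected = total * pm.frozen_price
            got = res.table.loc[code]["cost_without"].to_numpy()
            assert np.allclose(got, expected, rtol=1e-12)


class TestEquivarianceInvariants:
    def test_scale_equivariance_in_volumes(self):
        market = generate_market(SyntheticMarketConfig(seed=7, n_molecules=3))
        base = compute_bia(market.inputs)
        scaled = market.inputs
        k = 3.0
        scaled.uptake = scaled.uptake.assign(units=scaled.uptake["units"] * k)
        scaled.tenders = scaled.tenders.assign(
            volume_units=scaled.tenders["volume_units"] * k
        )
        res = compute_bia(scaled)
        scale = base.table["cost_without"].abs().max()
        assert np.allclose(
            res.table["savings"], k * base.table["savings"],
            rtol=1e-9, atol=1e-9 * k * scale,
        )

    def test_ddd_factor_price_rescaling_leaves_costs_unchanged(self):
        market = generate_market(SyntheticMarketConfig(seed=8, n_molecules=3))
        base = compute_bia(market.inputs)
        inputs = market.inputs
        # halve DDD content per unit, double every price per DDD
        new_mols = {}
        for code, m in inputs.molecules.items():
            new_mols[code] = type(m)(
                code=m.code, name=m.name, channel=m.channel,
                first_biosimilar_year_month=m.first_biosimilar_year_month,
                ddd_per_unit={k: v / 2 for k, v in m.ddd_per_unit.items()},
                discount_applicable=m.discount_applicable,
                pooled_components=m.pooled_components,
            )
        inputs.molecules = new_mols
        inputs.prices = inputs.prices.assign(efp_per_ddd=inputs.prices["efp_per_ddd"] * 2)
        inputs.rpo_events = inputs.rpo_events.assign(
            rp_per_ddd=inputs.rpo_events["rp_per_ddd"] * 2
        )
        res = compute_bia(inputs)
        assert np.allclose(
            res.table.to_numpy(), base.table.to_numpy(), rtol=1e-9
        )

    def test_more_biosimilar_uptake_never_reduces_savings(self):
        """Shifting demand toward the biosimilar is weakly
        savings-increasing whenever the biosimilar's annual net price does
        not exceed the originator's (savings change by the shifted volume
        times the net-price gap)."""
        from biosimbia.sensitivity import _scale_biosimilar_share

        market = generate_market(SyntheticMarketConfig(seed=9, n_molecules=4))
        prepared = prepare_market(market.inputs)
        base = compute_bia(prepared).total_savings()
        years = [int(y) for y in prepared.horizon.years]
        checked = 0
        for code, pm in prepared.molecules.items():
            eff = np.where(np.isnan(pm.prices), 0.0, pm.prices) * pm.weights
            net = eff.sum(axis=1) * (1 - pm.discount)  # (n_years, 2)
            has_bio = pm.ddd[:, 1] > 0
            if not (net[has_bio, 1] <= net[has_bio, 0] + 1e-9).all():
                continue
            up = compute_bia(
                _scale_biosimilar_share(prepared, code, years, 1.25)
            ).total_savings()
            assert up >= base - 1e-6
            checked += 1
        assert checked > 0


class TestDerivedQuantities:
    def test_published_table_subset_share(self):
        res_costs = fixture_from_table1()
        table = molecule_summary(res_costs)
        top3 = table.loc[["SOM", "EPO", "INF"], "savings"].sum()
        share = 100.0 * top3 / table.loc["TOTAL", "savings"]
        assert share == pytest.approx(61.3, abs=0.2)

    def test_share_full_set_and_empty_set(self, toy_market):
        res = compute_bia(toy_market)
        assert savings_share(res, ["TOY"]) == pytest.approx(100.0)
        assert savings_share(res, []) == 0.0

    def test_share_undefined_for_zero_total(self):
        from biosimbia.engine import BIAResult

        res = BIAResult.from_costs([("AAA", 2018, 5.0, 5.0)])
        with pytest.raises(ZeroDivisionError):
            savings_share(res, ["AAA"])

    def test_savings_vs_total_spend(self, toy_market):
        res = compute_bia(toy_market)
        pct = savings_vs_total_spend(res, {2010: 2000.0, 2011: 4800.0})
        assert pct.loc[2010] == pytest.approx(5.0)
        assert pct.loc[2011] == pytest.approx(5.0)

    def test_missing_spend_year_is_located_error(self, toy_market):
        res = compute_bia(toy_market)
        with pytest.raises(KeyError, match="2011"):
            savings_vs_total_spend(res, {2010: 2000.0})

    def test_mean_annual_savings_per_marketed_molecule(self, toy_market):
        res = compute_bia(toy_market)
        means = res.mean_annual_savings_per_marketed_molecule({"TOY": 2010})
        assert means.loc[2010] == pytest.approx(100.0)
        assert means.loc[2011] == pytest.approx(240.0)
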