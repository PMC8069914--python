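"""Tender-discount estimation and anchored regression backfill."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from biosimbia import (
    AnalysisHorizon,
    Channel,
    MoleculeSpec,
    ProductClass,
    annual_weighted_discount,
    assemble_discount_series,
    backfill_discounts_regression,
    discount_tier,
)
from biosimbia.discounts import Provenance
from biosimbia.errors import DiscountEstimationError

from conftest import hospital_molecule


def _flat_price(horizon, level=100.0):
    months = horizon.months
    s = pd.Series(level, index=months, dtype=float)
    return {ProductClass.originator: s, ProductClass.biosimilar: s}


def _tender(tid, pclass, award, start, end, price, vol):
    return (
        tid, "AAA", pclass, pd.Timestamp(award), pd.Period(start, freq="M"),
        pd.Period(end, freq="M"), price, vol, "",
    )


def _tender_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "tender_id", "code", "product_class", "award_date", "contract_start",
            "contract_end", "purchase_price_per_unit", "volume_units", "region",
        ],
    )


HORIZON = AnalysisHorizon(2015, 2019)


class TestAnnualWeightedDiscount:
    def test_hand_weighted_average(self):
        # awards at 50 and 100 against list 100: 1 - 1500/2000 = 0.25
        tenders = _tender_frame(
            [
                _tender("t1", "biosimilar", "2018-03-01", "2018-01", "2018-12", 50.0, 10.0),
                _tender("t2", "biosimilar", "2018-06-01", "2018-01", "2018-12", 100.0, 10.0),
            ]
        )
        d = annual_weighted_discount(tenders, _flat_price(HORIZON), 1.0, 2018)
        assert d[ProductClass.biosimilar] == pytest.approx(0.25)
        assert d[ProductClass.originator] is None  # no observation, not zero

    def test_award_at_list_price_is_zero_discount(self):
        tenders = _tender_frame(
            [_tender("t1", "originator", "2018-03-01", "2018-01", "2018-12", 100.0, 5.0)]
        )
        d = annual_weighted_discount(tenders, _flat_price(HORIZON), 1.0, 2018)
        assert d[ProductClass.originator] == pytest.approx(0.0)

    def test_contract_spreading_apportions_volume_by_months(self):
        # July 2018 - June 2019 contract: half the volume lands in each year
        tenders = _tender_frame(
            [_tender("t1", "biosimilar", "2018-07-02", "2018-07", "2019-06", 60.0, 12.0)]
        )
        for year in (2018, 2019):
            d = annual_weighted_discount(
                tenders, _flat_price(HORIZON), 1.0, year, spread_over_contract=True
            )
            assert d[ProductClass.biosimilar] == pytest.approx(0.4)
        d2018 = annual_weighted_discount(
            tenders, _flat_price(HORIZON), 1.0, 2018, spread_over_contract=False
        )
        d2019 = annual_weighted_discount(
            tenders, _flat_price(HORIZON), 1.0, 2019, spread_over_contract=False
        )
        assert d2018[ProductClass.biosimilar] == pytest.approx(0.4)
        assert d2019[ProductClass.biosimilar] is None  # all volume in award year

    def test_bid_above_list_clamps_to_zero_with_warning(self, caplog):
        tenders = _tender_frame(
            [_tender("t1", "biosimilar", "2018-03-01", "2018-01", "2018-12", 120.0, 5.0)]
        )
        with caplog.at_level("WARNING"):
            d = annual_weighted_discount(tenders, _flat_price(HORIZON), 1.0, 2018)
        assert d[ProductClass.biosimilar] == 0.0
        assert any("clamped" in r.message for r in caplog.records)

    @settings(deadline=None, derandomize=True)
    @given(
        price=st.floats(10.0, 99.0),
        vol=st.floats(1.0, 100.0),
        split=st.floats(0.05, 0.95),
    )
    def test_split_invariance(self, price, vol, split):
        """Splitting one award into two at the same price leaves the discount unchanged."""
        whole = _tender_frame(
            [_tender("t", "biosimilar", "2018-03-01", "2018-01", "2018-12", price, vol)]
        )
        parts = _tender_frame(
            [
                _tender("a", "biosimilar", "2018-03-01", "2018-01", "2018-12", price, vol * split),
                _tender("b", "biosimilar", "2018-03-01", "2018-01", "2018-12", price, vol * (1 - split)),
            ]
        )
        d1 = annual_weighted_discount(whole, _flat_price(HORIZON), 1.0, 2018)
        d2 = annual_weighted_discount(parts, _flat_price(HORIZON), 1.0, 2018)
        assert d1[ProductClass.biosimilar] == pytest.approx(
            d2[ProductClass.biosimilar], rel=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(
        prices=st.lists(st.floats(10.0, 100.0), min_size=2, max_size=6),
        vols=st.lists(st.floats(1.0, 50.0), min_size=2, max_size=6),
    )
    def test_weighted_discount_is_convex_combination(self, prices, vols):
        n = min(len(prices), len(vols))
        rows = [
            _tender(f"t{i}", "biosimilar", "2018-03-01", "2018-01", "2018-12",
                    prices[i], vols[i])
            for i in range(n)
        ]
        d = annual_weighted_discount(
            _tender_frame(rows), _flat_price(HORIZON), 1.0, 2018
        )[ProductClass.biosimilar]
        per_award = [1.0 - p / 100.0 for p in prices[:n]]
        assert min(per_award) - 1e-12 <= d <= max(per_award) + 1e-12


class TestRegressionBackfill:
    def test_closed_form_matches_brute_force_grid(self):
        observed = {2018: 0.40, 2019: 0.50}
        series, beta = backfill_discounts_regression(observed, 2008, range(2009, 2020))
        # frozen closed-form value: (10*0.40 + 11*0.50) / (100 + 121)
        assert beta == pytest.approx(9.5 / 221)
        assert series[2016] == pytest.approx(8 * 9.5 / 221)  # ~0.3439
        # independent oracle: grid search over the slope minimising SSE
        grid = np.linspace(0.0, 0.1, 200001)
        sse = [
            sum((d - b * (y - 2008)) ** 2 for y, d in observed.items()) for b in grid
        ]
        assert grid[int(np.argmin(sse))] == pytest.approx(beta, abs=1e-6)

    def test_zero_observation_gives_flat_zero_series(self):
        series, beta = backfill_discounts_regression({2009: 0.0}, 2008, range(2009, 2015))
        assert beta == 0.0 and all(v == 0.0 for v in series.values())

    def test_single_observation_is_proportional_through_anchor(self):
        series, _ = backfill_discounts_regression({2019: 0.55}, 2014, range(2015, 2020))
        assert series[2017] == pytest.approx(0.55 * 3 / 5)

    def test_anchor_year_itself_predicts_zero(self):
        series, _ = backfill_discounts_regression({2019: 0.55}, 2014, [2014, 2016])
        assert series[2014] == 0.0

    def test_extrapolation_clamped_to_cap(self):
        series, _ = backfill_discounts_regression({2015: 0.9}, 2014, [2030])
        assert series[2030] == 0.95

    def test_observed_years_override_the_fit(self):
        observed = {2016: 0.10, 2019: 0.80}
        series, _ = backfill_discounts_regression(observed, 2014, range(2015, 2020))
        assert series[2016] == 0.10 and series[2019] == 0.80

    def test_no_observations_is_an_error(self):
        with pytest.raises(DiscountEstimationError):
            backfill_discounts_regression({}, 2014, [2015])

    def test_pseudo_observation_variant_agrees_here(self):
        # the anchor contributes (t=0, d=0): both fits coincide exactly
        observed = {2018: 0.4, 2019: 0.5}
        _, b1 = backfill_discounts_regression(observed, 2008, [2016], method="constrained")
        _, b2 = backfill_discounts_regression(observed, 2008, [2016], method="ols_pseudo")
        assert b1 == pytest.approx(b2)

    @settings(deadline=None, derandomize=True)
    @given(
        beta=st.floats(0.01, 0.08),
        years=st.lists(st.integers(2016, 2019), min_size=1, max_size=4, unique=True),
    )
    def test_noise_free_linear_trajectory_recovered_exactly(self, beta, years):
        anchor = 2014
        observed = {y: beta * (y - anchor) for y in years}
        series, fitted = backfill_discounts_regression(observed, anchor, range(2015, 2020))
        assert fitted == pytest.approx(beta, rel=1e-12)
        for y in range(2015, 2020):
            assert series[y] == pytest.approx(beta * (y - anchor), rel=1e-9)


class TestAssembleDiscountSeries:
    def test_retail_molecule_gets_zero_series_by_channel(self):
        retail = MoleculeSpec(
            code="INS", name="insulin glargine", channel=Channel.retail,
            first_biosimilar_year_month=pd.Period("2015-09", freq="M"),
            ddd_per_unit={"P1": 1.0}, discount_applicable=False,
        )
        ds = assemble_discount_series(
            retail, _tender_frame([]), pd.DataFrame(
                columns=["code", "product_class", "year", "discount_fraction"]
            ), _flat_price(HORIZON), HORIZON,
        )
        assert (ds.values.to_numpy() == 0.0).all()
        assert (ds.provenance.to_numpy() == Provenance.zero_by_channel.value).all()

    def test_partial_coverage_backfilled_by_regression(self):
        mol = hospital_molecule(launch="2016-01")
        tenders = _tender_frame(
            [
                _tender("t1", "biosimilar", "2018-02-01", "2018-01", "2018-12", 60.0, 10.0),
                _tender("t2", "biosimilar", "2019-02-01", "2019-01", "2019-12", 50.0, 10.0),
                _tender("t3", "originator", "2018-02-01", "2018-01", "2018-12", 80.0, 10.0),
                _tender("t4", "originator", "2019-02-01", "2019-01", "2019-12", 80.0, 10.0),
            ]
        )
        ds = assemble_discount_series(
            mol, tenders, pd.DataFrame(
                columns=["code", "product_class", "year", "discount_fraction"]
            ), _flat_price(HORIZON), HORIZON,
        )
        bio = ds.values["biosimilar"]
        prov = ds.provenance["biosimilar"]
        assert prov.loc[2018] == prov.loc[2019] == Provenance.observed.value
        assert prov.loc[2016] == prov.loc[2017] == Provenance.regressed.value
        assert bio.loc[2015] == 0.0  # pre-launch year sits at/below the anchor
        # anchored line: beta = (3*0.4 + 4*0.5)/(9+16)
        beta = (3 * 0.4 + 4 * 0.5) / 25
        assert bio.loc[2016] == pytest.approx(beta * 1)
        assert bio.loc[2017] == pytest.approx(beta * 2)

    def test_full_coverage_is_all_observed(self):
        mol = hospital_molecule(launch="2015-01")
        rows = [
            _tender(f"t{y}", "biosimilar", f"{y}-02-01", f"{y}-01", f"{y}-12", 70.0, 10.0)
            for y in range(2015, 2020)
        ] + [
            _tender(f"o{y}", "originator", f"{y}-02-01", f"{y}-01", f"{y}-12", 90.0, 10.0)
            for y in range(2015, 2020)
        ]
        ds = assemble_discount_series(
            mol, _tender_frame(rows), pd.DataFrame(
                columns=["code", "product_class", "year", "discount_fraction"]
            ), _flat_price(HORIZON), HORIZON,
        )
        assert (ds.provenance.to_numpy() == Provenance.observed.value).all()

    def test_hospital_molecule_without_any_observation_is_an_error(self):
        mol = hospital_molecule(launch="2016-01")
        with pytest.raises(DiscountEstimationError):
            assemble_discount_series(
                mol, _tender_frame([]), pd.DataFrame(
                    columns=["code", "product_class", "year", "discount_fraction"]
                ), _flat_price(HORIZON), HORIZON,
            )


class TestDiscountTier:
    @pytest.mark.parametrize(
        ("fraction", "tier"),
        [(0.0, "+"), (0.10, "+"), (0.249, "+"), (0.25, "++"), (0.49, "++"),
         (0.50, "++"), (0.501, "+++"), (0.80, "+++")],
    )
    def test_band_classification(self, fraction, tier):
        assert discount_tier(fraction) == tier
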