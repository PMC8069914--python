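import numpy as np
import pandas as pd
import pytest

from biosimbia import AnalysisHorizon, Channel, MarketInputs, MoleculeSpec


def make_inputs(
    molecules: dict[str, MoleculeSpec],
    horizon: AnalysisHorizon,
    uptake_rows=(),
    price_rows=(),
    rpo_rows=(),
    tender_rows=(),
    override_rows=(),
) -> MarketInputs:
    """Assemble a MarketInputs from terse row tuples.

    uptake: (code, year, class, units[, presentation]);
    prices: (code, class, "YYYY-MM", efp_per_ddd);
    rpos: (code, "YYYY-MM-DD", rp_per_ddd);
    tenders: (tid, code, class, "YYYY-MM-DD", "YYYY-MM", "YYYY-MM", price, vol);
    overrides: (code, class, year, fraction).
    """
    uptake = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4] if len(r) > 4 else "") for r in uptake_rows],
        columns=["code", "year", "product_class", "units", "presentation_id"],
    )
    prices = pd.DataFrame(
        [(c, pc, pd.Period(m, freq="M"), p) for c, pc, m, p in price_rows],
        columns=["code", "product_class", "effective_month", "efp_per_ddd"],
    )
    rpos = pd.DataFrame(
        [(c, pd.Timestamp(d), rp) for c, d, rp in rpo_rows],
        columns=["code", "publication_date", "rp_per_ddd"],
    )
    tenders = pd.DataFrame(
        [
            (t[0], t[1], t[2], pd.Timestamp(t[3]), pd.Period(t[4], freq="M"),
             pd.Period(t[5], freq="M"), t[6], t[7], "")
            for t in tender_rows
        ],
        columns=[
            "tender_id", "code", "product_class", "award_date", "contract_start",
            "contract_end", "purchase_price_per_unit", "volume_units", "region",
        ],
    )
    overrides = pd.DataFrame(
        list(override_rows),
        columns=["code", "product_class", "year", "discount_fraction"],
    )
    return MarketInputs(
        horizon=horizon, molecules=molecules, uptake=uptake, prices=prices,
        rpo_events=rpos, tenders=tenders, discount_overrides=overrides,
    )


def hospital_molecule(code="AAA", launch="2015-01", factor=1.0, **kw) -> MoleculeSpec:
    return MoleculeSpec(
        code=code,
        name=f"test molecule {code}",
        channel=Channel.hospital,
        first_biosimilar_year_month=pd.Period(launch, freq="M"),
        ddd_per_unit={"P1": factor},
        discount_applicable=True,
        **kw,
    )


@pytest.fixture
def toy_market() -> MarketInputs:
    """One originator-only molecule, two years, fully controlled numbers.

    Counterfactual 1000/year (100 DDD x frozen 10); actual year 1:
    100 x 10 x (1-0.1) = 900; year 2: RP 9.5 effective 2011-01 and
    discount 0.2 give 100 x 9.5 x 0.8 = 760. Savings 100 and 240.
    """
    mol = hospital_molecule("TOY", launch="2010-01")
    return make_inputs(
        {"TOY": mol},
        AnalysisHorizon(2010, 2011),
        uptake_rows=[
            ("TOY", 2010, "originator", 100.0, "P1"),
            ("TOY", 2011, "originator", 100.0, "P1"),
            ("TOY", 2010, "biosimilar", 0.0, "P1"),
            ("TOY", 2011, "biosimilar", 0.0, "P1"),
        ],
        price_rows=[("TOY", "originator", "2010-01", 10.0)],
        rpo_rows=[("TOY", "2010-12-20", 9.5)],
        override_rows=[
            ("TOY", "originator", 2010, 0.1),
            ("TOY", "originator", 2011, 0.2),
            ("TOY", "biosimilar", 2010, 0.0),
            ("TOY", "biosimilar", 2011, 0.0),
        ],
    )
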