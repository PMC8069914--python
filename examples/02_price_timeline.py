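"""List-price timeline under the reference-price system.

Shows the three pricing rules on a hand-built molecule: the day-15
effective-month rule for a reference-price order (RPO), the replacement
of the ex-factory price (EFP) by the reference price (RP) for both
product classes, and the 10% imputation of an unobserved biosimilar
price before its first RPO.
"""

import pandas as pd

from biosimbia import (
    AnalysisHorizon,
    Channel,
    MoleculeSpec,
    ProductClass,
    build_price_timeline,
    counterfactual_price_timeline,
    rpo_effective_month,
)

molecule = MoleculeSpec(
    code="DEMO", name="demo biological", channel=Channel.hospital,
    first_biosimilar_year_month=pd.Period("2016-03", freq="M"),
    ddd_per_unit={"P1": 1.0}, discount_applicable=True,
)
horizon = AnalysisHorizon(2016, 2017)
efp = pd.DataFrame(
    [("originator", pd.Period("2016-01", freq="M"), 10.0)],
    columns=["product_class", "effective_month", "efp_per_ddd"],
)
rpos = pd.DataFrame(
    [(pd.Timestamp("2016-12-20"), 8.0)], columns=["publication_date", "rp_per_ddd"]
)

print("RPO published 2016-12-20 takes effect:", rpo_effective_month("2016-12-20"))
timeline = build_price_timeline(molecule, efp, rpos, horizon)
frozen = counterfactual_price_timeline(molecule, efp, horizon)

table = pd.DataFrame(
    {
        "originator": timeline[ProductClass.originator],
        "biosimilar": timeline[ProductClass.biosimilar],
        "counterfactual": frozen,
    }
)
print(table.loc["2016-02":"2017-02"].to_string())
print()
print(
    "The biosimilar launches 2016-03 with no observed price, so its\n"
    "pre-RPO months are imputed at RP x 1.10 = 8.80 EUR/DDD; from the\n"
    "RPO's effective month (2017-01, day-15 rule) both classes share the\n"
    "RP of 8.00, while the counterfactual keeps the frozen 10.00."
)
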