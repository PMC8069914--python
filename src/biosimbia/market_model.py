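"""Domain types and CSV interchange for biosimilar market data.

The analysis compares pharmaceutical payer costs in two worlds: the actual
market, where biosimilars erode prices through the reference-price system
and hospital tender discounts, and a counterfactual market where the
originator keeps its pre-entry list price and all demand. This module
holds the static description of each molecule market, the analysis
horizon, consumption series, and the readers/writers for the documented
CSV schemas. All validation is total: a violated invariant raises a
located error, never a silent coercion.

Units convention: consumption arrives as dispensed units per presentation
and is converted to WHO defined daily doses (DDD) at read time, so every
downstream stage works in DDDs and EUR/DDD.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputValidationError, ReferentialError, SchemaError

__all__ = [
    "Channel",
    "ProductClass",
    "AnalysisHorizon",
    "MoleculeSpec",
    "MarketInputs",
    "read_market_inputs",
    "write_market_inputs",
    "molecule_summary",
    "write_report_tables",
    "read_report_table",
]


class Channel(str, enum.Enum):
    """Dispensing channel; retail pharmacies carry no tender discounts."""

    hospital = "hospital"
    retail = "retail"


class ProductClass(str, enum.Enum):
    """Every price, discount and uptake record belongs to one class."""

    originator = "originator"
    biosimilar = "biosimilar"


CLASSES = (ProductClass.originator, ProductClass.biosimilar)


@dataclass(frozen=True)
class AnalysisHorizon:
    """Inclusive year range of the analysis with a derived monthly grid."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise InputValidationError(
                f"horizon start {self.start_year} after end {self.end_year}"
            )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(
            start=f"{self.start_year}-01", end=f"{self.end_year}-12", freq="M"
        )


@dataclass(frozen=True)
class MoleculeSpec:
    """Static description of one molecule market.

    ``ddd_per_unit`` maps presentation id to the number of DDDs contained
    in one dispensed unit of that presentation. ``pooled_components`` lists
    sub-molecule codes merged into this code at read time (e.g. two epoetin
    variants marketed as one reference group).
    """

    code: str
    name: str
    channel: Channel
    first_biosimilar_year_month: pd.Period
    ddd_per_unit: Mapping[str, float]
    discount_applicable: bool
    pooled_components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for pres, factor in self.ddd_per_unit.items():
            if not factor > 0:
                raise InputValidationError(
                    f"molecule {self.code}: ddd_per_unit must be > 0 "
                    f"(presentation {pres!r} has {factor})"
                )
        if self.channel is Channel.retail and self.discount_applicable:
            raise InputValidationError(
                f"molecule {self.code}: retail channel molecules cannot have "
                "discount_applicable=true"
            )

    @property
    def launch_year(self) -> int:
        return self.first_biosimilar_year_month.year

    def mean_ddd_factor(self) -> float:
        """DDD-per-unit factor used for tender unit prices.

        Tenders are quoted per unit without a presentation id; the mean
        factor across presentations serves as the reference-presentation
        conversion. The derived discount is a price ratio, so any
        consistent conversion cancels out.
        """
        return float(np.mean(list(self.ddd_per_unit.values())))


# --------------------------------------------------------------------------
# CSV schemas


_SCHEMAS: dict[str, list[str]] = {
    "molecules": ["code", "name", "channel", "first_biosimilar_year_month", "discount_applicable"],
    "ddd_factors": ["code", "presentation_id", "ddd_per_unit"],
    "uptake": ["code", "year", "product_class", "units"],
    "prices": ["code", "product_class", "effective_year_month", "efp_per_ddd"],
    "rpo_events": ["code", "publication_date", "rp_per_ddd"],
    "tenders": [
        "tender_id", "code", "product_class", "award_date", "contract_start",
        "contract_end", "purchase_price_per_unit", "volume_units",
    ],
    "discount_overrides": ["code", "product_class", "year", "discount_fraction"],
}


def _require_columns(df: pd.DataFrame, table: str) -> None:
    for col in _SCHEMAS[table]:
        if col not in df.columns:
            raise SchemaError(f"{table}.csv: missing required column {col!r}")


def _read_csv(path: Path, table: str, required: bool = True) -> pd.DataFrame:
    f = path / f"{table}.csv"
    if not f.exists():
        if required:
            raise SchemaError(f"missing input file: {f}")
        return pd.DataFrame(columns=_SCHEMAS[table])
    df = pd.read_csv(f, dtype={"code": str})
    if df.empty and list(df.columns) == []:
        return pd.DataFrame(columns=_SCHEMAS[table])
    _require_columns(df, table)
    return df


@dataclass
class MarketInputs:
    """Fully validated in-memory model of one market input directory."""

    horizon: AnalysisHorizon
    molecules: dict[str, MoleculeSpec]
    uptake: pd.DataFrame           # code, year, product_class, units, presentation_id
    prices: pd.DataFrame           # code, product_class, effective_month (Period), efp_per_ddd
    rpo_events: pd.DataFrame       # code, publication_date (Timestamp), rp_per_ddd
    tenders: pd.DataFrame          # tender_id, code, product_class, award_date,
                                   # contract_start/end (Period), purchase_price_per_unit, volume_units
    discount_overrides: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_SCHEMAS["discount_overrides"])
    )

    def ddd_volumes(self) -> pd.DataFrame:
        """Convert unit-level uptake to a DDD volume table.

        Returns a frame indexed by (code, year) with columns
        ``ddd_originator`` and ``ddd_biosimilar``. Zero rows are kept for
        every horizon year so partial-entry years read as zero, not
        missing.
        """
        from .engine import convert_units_to_ddd  # local import: avoid cycle

        return convert_units_to_ddd(self.uptake, self.molecules, self.horizon)


def _parse_period(value: str, table: str, row: int) -> pd.Period:
    try:
        return pd.Period(str(value), freq="M")
    except Exception as exc:  # noqa: BLE001 - re-raise located
        raise InputValidationError(
            f"cannot parse year-month {value!r}", table=table, row=row
        ) from exc


def read_market_inputs(
    path: str | Path,
    horizon: AnalysisHorizon | None = None,
    schema_version: str = "1",
) -> MarketInputs:
    """Read and validate a market input directory.

    The directory holds ``molecules.csv``, ``ddd_factors.csv``,
    ``uptake.csv``, ``prices.csv`` and optionally ``rpo_events.csv``,
    ``tenders.csv``, ``discount_overrides.csv`` and ``horizon.json``.
    Pooled component codes are remapped to their pooled molecule at read
    time, so downstream stages only ever see pooled codes.
    """
    if schema_version != "1":
        raise SchemaError(f"unsupported schema_version {schema_version!r}")
    path = Path(path)

    mol_df = _read_csv(path, "molecules")
    fac_df = _read_csv(path, "ddd_factors")
    uptake = _read_csv(path, "uptake", required=False)
    prices = _read_csv(path, "prices")
    rpos = _read_csv(path, "rpo_events", required=False)
    tenders = _read_csv(path, "tenders", required=False)
    overrides = _read_csv(path, "discount_overrides", required=False)

    if horizon is None:
        hfile = path / "horizon.json"
        if hfile.exists():
            h = json.loads(hfile.read_text())
            horizon = AnalysisHorizon(int(h["start_year"]), int(h["end_year"]))
        elif len(uptake):
            horizon = AnalysisHorizon(int(uptake["year"].min()), int(uptake["year"].max()))
        else:
            raise SchemaError("no horizon given: provide horizon.json or an uptake table")

    # --- DDD factors -------------------------------------------------------
    factors: dict[str, dict[str, float]] = {}
    for i, r in fac_df.iterrows():
        if not float(r["ddd_per_unit"]) > 0:
            raise InputValidationError(
                f"nonpositive ddd_per_unit {r['ddd_per_unit']}", table="ddd_factors", row=int(i)
            )
        factors.setdefault(str(r["code"]), {})[str(r["presentation_id"])] = float(r["ddd_per_unit"])

    # --- molecules ---------------------------------------------------------
    molecules: dict[str, MoleculeSpec] = {}
    alias: dict[str, str] = {}  # component code -> pooled code
    for i, r in mol_df.iterrows():
        code = str(r["code"])
        try:
            channel = Channel(str(r["channel"]))
        except ValueError as exc:
            raise InputValidationError(
                f"unknown channel {r['channel']!r}", table="molecules", row=int(i)
            ) from exc
        pooled = ()
        if "pooled_components" in mol_df.columns and isinstance(r.get("pooled_components"), str):
            pooled = tuple(c for c in str(r["pooled_components"]).split(";") if c)
        launch = _parse_period(r["first_biosimilar_year_month"], "molecules", int(i))
        if launch.year > horizon.end_year:
            raise InputValidationError(
                f"molecule {code}: first biosimilar {launch} is after the horizon end",
                table="molecules", row=int(i),
            )
        mol_factors = dict(factors.get(code, {}))
        for comp in pooled:
            mol_factors.update(factors.get(comp, {}))
            alias[comp] = code
        if not mol_factors:
            raise ReferentialError(f"molecule {code}: no DDD factors in ddd_factors.csv")
        molecules[code] = MoleculeSpec(
            code=code,
            name=str(r["name"]),
            channel=channel,
            first_biosimilar_year_month=launch,
            ddd_per_unit=mol_factors,
            discount_applicable=bool(r["discount_applicable"]),
            pooled_components=pooled,
        )

    def resolve(code: str, table: str, row: int) -> str:
        code = alias.get(code, code)
        if code not in molecules:
            raise ReferentialError(
                f"unknown molecule code {code!r} in {table}.csv (row {row})"
            )
        return code

    # --- uptake ------------------------------------------------------------
    uptake = uptake.copy()
    if "presentation_id" not in uptake.columns:
        uptake["presentation_id"] = ""
    up_rows = []
    for i, r in uptake.iterrows():
        code = resolve(str(r["code"]), "uptake", int(i))
        units = float(r["units"])
        if units < 0:
            raise InputValidationError(f"negative units {units}", table="uptake", row=int(i))
        try:
            pclass = ProductClass(str(r["product_class"]))
        except ValueError as exc:
            raise InputValidationError(
                f"unknown product_class {r['product_class']!r}", table="uptake", row=int(i)
            ) from exc
        year = int(r["year"])
        if not (horizon.start_year <= year <= horizon.end_year):
            raise InputValidationError(
                f"uptake year {year} outside horizon", table="uptake", row=int(i)
            )
        if (
            pclass is ProductClass.biosimilar
            and units > 0
            and year < molecules[code].launch_year
        ):
            raise InputValidationError(
                f"molecule {code}: biosimilar units in {year}, before first "
                f"biosimilar marketing {molecules[code].first_biosimilar_year_month}",
                table="uptake", row=int(i),
            )
        pres = str(r["presentation_id"]) if r["presentation_id"] else ""
        up_rows.append((code, year, pclass.value, units, pres))
    uptake = pd.DataFrame(
        up_rows, columns=["code", "year", "product_class", "units", "presentation_id"]
    )

    # --- prices ------------------------------------------------------------
    pr_rows = []
    for i, r in prices.iterrows():
        code = resolve(str(r["code"]), "prices", int(i))
        price = float(r["efp_per_ddd"])
        if not price > 0:
            raise InputValidationError(f"nonpositive price {price}", table="prices", row=int(i))
        pclass = ProductClass(str(r["product_class"]))
        month = _parse_period(r["effective_year_month"], "prices", int(i))
        pr_rows.append((code, pclass.value, month, price))
    prices = pd.DataFrame(
        pr_rows, columns=["code", "product_class", "effective_month", "efp_per_ddd"]
    )
    dup = prices.duplicated(["code", "product_class", "effective_month"])
    if dup.any():
        raise InputValidationError(
            "duplicate effective month for one (molecule, class)",
            table="prices", row=int(dup.idxmax()),
        )

    # --- reference price orders --------------------------------------------
    rpo_rows = []
    for i, r in rpos.iterrows():
        code = resolve(str(r["code"]), "rpo_events", int(i))
        rp = float(r["rp_per_ddd"])
        if not rp > 0:
            raise InputValidationError(f"nonpositive RP {rp}", table="rpo_events", row=int(i))
        rpo_rows.append((code, pd.Timestamp(r["publication_date"]), rp))
    rpos = pd.DataFrame(rpo_rows, columns=["code", "publication_date", "rp_per_ddd"])

    # --- tenders ------------------------------------------------------------
    td_rows = []
    for i, r in tenders.iterrows():
        code = resolve(str(r["code"]), "tenders", int(i))
        vol = float(r["volume_units"])
        if not vol > 0:
            raise InputValidationError(f"nonpositive volume {vol}", table="tenders", row=int(i))
        price = float(r["purchase_price_per_unit"])
        if not price > 0:
            raise InputValidationError(
                f"nonpositive purchase price {price}", table="tenders", row=int(i)
            )
        start = _parse_period(r["contract_start"], "tenders", int(i))
        end = _parse_period(r["contract_end"], "tenders", int(i))
        if start > end:
            raise InputValidationError(
                f"contract_start {start} after contract_end {end}", table="tenders", row=int(i)
            )
        td_rows.append(
            (
                str(r["tender_id"]), code, ProductClass(str(r["product_class"])).value,
                pd.Timestamp(r["award_date"]), start, end, price, vol,
                str(r["region"]) if "region" in tenders.columns and pd.notna(r.get("region")) else "",
            )
        )
    tenders = pd.DataFrame(
        td_rows,
        columns=[
            "tender_id", "code", "product_class", "award_date", "contract_start",
            "contract_end", "purchase_price_per_unit", "volume_units", "region",
        ],
    )

    # --- overrides -----------------------------------------------------------
    ov_rows = []
    for i, r in overrides.iterrows():
        code = resolve(str(r["code"]), "discount_overrides", int(i))
        d = float(r["discount_fraction"])
        if not (0 <= d < 1):
            raise InputValidationError(
                f"discount_fraction {d} outside [0, 1)", table="discount_overrides", row=int(i)
            )
        ov_rows.append((code, ProductClass(str(r["product_class"])).value, int(r["year"]), d))
    overrides = pd.DataFrame(
        ov_rows, columns=["code", "product_class", "year", "discount_fraction"]
    )

    return MarketInputs(
        horizon=horizon,
        molecules=molecules,
        uptake=uptake,
        prices=prices,
        rpo_events=rpos,
        tenders=tenders,
        discount_overrides=overrides,
    )


def write_market_inputs(inputs: MarketInputs, path: str | Path) -> None:
    """Write a :class:`MarketInputs` back to the CSV interchange layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    mol_rows, fac_rows = [], []
    for m in inputs.molecules.values():
        mol_rows.append(
            {
                "code": m.code,
                "name": m.name,
                "channel": m.channel.value,
                "first_biosimilar_year_month": str(m.first_biosimilar_year_month),
                "discount_applicable": m.discount_applicable,
                "pooled_components": ";".join(m.pooled_components),
            }
        )
        for pres, f in m.ddd_per_unit.items():
            fac_rows.append({"code": m.code, "presentation_id": pres, "ddd_per_unit": f})
    pd.DataFrame(mol_rows).to_csv(path / "molecules.csv", index=False)
    pd.DataFrame(fac_rows).to_csv(path / "ddd_factors.csv", index=False)

    up = inputs.uptake.copy()
    up.to_csv(path / "uptake.csv", index=False)

    pr = inputs.prices.copy()
    pr["effective_year_month"] = pr["effective_month"].astype(str)
    pr[["code", "product_class", "effective_year_month", "efp_per_ddd"]].to_csv(
        path / "prices.csv", index=False
    )

    rp = inputs.rpo_events.copy()
    if len(rp):
        rp["publication_date"] = rp["publication_date"].dt.date.astype(str)
    rp.to_csv(path / "rpo_events.csv", index=False)

    td = inputs.tenders.copy()
    if len(td):
        td["award_date"] = td["award_date"].dt.date.astype(str)
        td["contract_start"] = td["contract_start"].astype(str)
        td["contract_end"] = td["contract_end"].astype(str)
    td.to_csv(path / "tenders.csv", index=False)

    inputs.discount_overrides.to_csv(path / "discount_overrides.csv", index=False)
    (path / "horizon.json").write_text(
        json.dumps(
            {"start_year": inputs.horizon.start_year, "end_year": inputs.horizon.end_year}
        )
    )


# --------------------------------------------------------------------------
# Report tables


def molecule_summary(costs: pd.DataFrame) -> pd.DataFrame:
    """Per-molecule savings table with a TOTAL row.

    ``costs`` is indexed by molecule code with columns ``cost_without``
    and ``cost_with`` (any currency scale). Savings are recomputed as the
    column difference and the TOTAL row as full-precision column sums, so
    aggregate identities hold to machine precision before any rounding.
    """
    out = costs[["cost_without", "cost_with"]].copy()
    out["savings"] = out["cost_without"] - out["cost_with"]
    out.loc["TOTAL"] = out.sum(axis=0)
    return out


def write_report_tables(
    result, path: str | Path, decimals: int | None = None
) -> Path:
    """Write the per-molecule summary of a BIA result as CSV.

    ``result`` may be a BIAResult or a per-molecule cost frame. Full
    precision by default; pass ``decimals`` to round for presentation
    (reports print EUR million with 2 decimals).
    """
    costs = result.per_molecule() if hasattr(result, "per_molecule") else result
    table = molecule_summary(costs)
    if decimals is not None:
        table = table.round(decimals)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index_label="molecule")
    return path


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Read back a summary written by :func:`write_report_tables`."""
    return pd.read_csv(path, index_col="molecule")
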