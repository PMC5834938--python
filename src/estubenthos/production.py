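"""Biomass (AFDW) and allometric secondary-production estimation.

Macrofaunal wet weights, recorded per taxon x sieve-class fraction, are
converted to ash-free dry weight (AFDW) with taxon-group conversion
factors, then daily production is estimated with the general allometric
model

    P = a * B^b * T^c        (P in ug day^-1, B in ug AFDW, T in degC)

with a = 0.0049, b = 0.80, c = 0.89, applied per individual: B is the
mean individual AFDW of a taxon x sieve fraction and the result is
multiplied by the fraction's abundance (the size-class method; sieve
fractionation makes each fraction approximately one body-size class).
Temperature is standardized at 23.5 degC by default.  Annual turnover
P/B = 365 * mean daily production / mean standing biomass.

Unit conventions: wet weights are stored in mg; the allometric equation
is evaluated in ug; areal outputs are mg AFDW m^-2 (biomass) and
mg m^-2 day^-1 (production).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import KEY_COLUMNS, SurveyDesign

#: the six report groups used for biomass / production summaries
REPORT_GROUPS = (
    "Polychaeta", "Oligochaeta", "Kalliapseudidae",
    "Other Crustacea", "Mollusca", "Others",
)

# Default AFDW : wet-weight ratios per report group, compiled from the
# standard conversion-factor literature for soft-bottom macrofauna
# (mollusk values are shell-free flesh).  Editable; see docs/methods.md.
DEFAULT_CONVERSION_FACTORS: dict[str, float] = {
    "Polychaeta": 0.155,
    "Oligochaeta": 0.150,
    "Kalliapseudidae": 0.175,
    "Other Crustacea": 0.175,
    "Mollusca": 0.120,
    "Others": 0.150,
}
CONVERSION_TABLE_VERSION = "default-2024.1"


class UnknownTaxonError(KeyError):
    """A taxon has no entry in the group map / conversion table."""


_MOLLUSC_FAMILIES = {"Mytilidae", "Solecurtidae", "Tellinidae", "Lucinidae"}
_CRUSTACEAN_FAMILIES = {
    "Panopeidae", "Ocypodidae", "Corophiidae", "Gammaridae", "Melitidae",
    "Sphaeromatidae", "Cirolanidae",
}
_POLYCHAETE_FAMILIES = {
    "Capitellidae", "Spionidae", "Nereididae", "Ampharetidae", "Pilargidae",
    "Goniadidae", "Glyceridae", "Orbiniidae", "Paraonidae", "Cossuridae",
    "Maldanidae", "Opheliidae", "Phyllodocidae", "Hesionidae", "Magelonidae",
    "Oweniidae", "Onuphidae", "Eunicidae", "Sternaspidae", "Syllidae",
    "Sabellidae",
}


def default_group_map(taxa) -> dict[str, str]:
    """Map taxon labels onto the six report groups.

    Known polychaete, crustacean and mollusk families are classified by
    membership lists; labels starting with 'Polychaeta' count as
    Polychaeta; Oligochaeta and Kalliapseudidae map to themselves;
    anything else lands in 'Others'.
    """
    out = {}
    for t in taxa:
        if t in ("Oligochaeta", "Kalliapseudidae"):
            out[t] = t
        elif t in _MOLLUSC_FAMILIES:
            out[t] = "Mollusca"
        elif t in _CRUSTACEAN_FAMILIES:
            out[t] = "Other Crustacea"
        elif t in _POLYCHAETE_FAMILIES or t.startswith("Polychaeta"):
            out[t] = "Polychaeta"
        else:
            out[t] = "Others"
    return out


@dataclass(frozen=True)
class ConversionTable:
    """Taxon-group -> AFDW/wet-weight factors plus a version tag that is
    echoed in every output."""

    factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONVERSION_FACTORS)
    )
    version: str = CONVERSION_TABLE_VERSION

    def __post_init__(self) -> None:
        for group, f in self.factors.items():
            if not 0 < f <= 1:
                raise ValueError(f"conversion factor for {group!r} must be in (0, 1]")

    def factor(self, group: str) -> float:
        try:
            return self.factors[group]
        except KeyError:
            raise UnknownTaxonError(
                f"no AFDW conversion factor for group {group!r}; "
                f"known groups: {sorted(self.factors)}"
            ) from None

    @classmethod
    def from_csv(cls, path: str | Path, version: str | None = None) -> "ConversionTable":
        df = pd.read_csv(path)
        return cls(
            factors=dict(zip(df["taxon_group"], df["afdw_factor"])),
            version=version or str(path),
        )


@dataclass(frozen=True)
class ProductionParams:
    """Allometric model constants and the annualization convention."""

    T: float = 23.5          # water temperature, degC (standardized)
    a: float = 0.0049
    b: float = 0.80
    c: float = 0.89
    days_per_year: float = 365.0
    #: 'individual' evaluates B as mean individual AFDW and multiplies by
    #: abundance (size-class method, default); 'whole_fraction' evaluates
    #: the fraction's summed AFDW directly.  The two differ by N^(1-b).
    mode: str = "individual"

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive (degC)")
        if self.mode not in ("individual", "whole_fraction"):
            raise ValueError("mode must be 'individual' or 'whole_fraction'")

    def with_temperature(self, T: float) -> "ProductionParams":
        return replace(self, T=T)


def afdw_from_wet(wet_weight_mg, group, table: ConversionTable):
    """Convert wet weight (mg) to AFDW (mg) by the group's factor."""
    return np.asarray(wet_weight_mg, dtype=float) * table.factor(group)


def edgar_individual_production(B_ind_ug, params: ProductionParams = ProductionParams()):
    """Daily production (ug day^-1) of one individual of AFDW ``B_ind_ug`` (ug)."""
    B = np.asarray(B_ind_ug, dtype=float)
    if np.any(B < 0):
        raise ValueError("individual AFDW must be non-negative")
    return params.a * B ** params.b * params.T ** params.c


def fraction_production(count, fraction_afdw_ug, params: ProductionParams = ProductionParams()):
    """Daily production (ug day^-1) of one taxon x sieve fraction in one core.

    ``fraction_afdw_ug`` is the fraction's total AFDW.  In the default
    per-individual mode: ``count * P(fraction_afdw / count)``; zero when
    the fraction is empty.  Biomass with zero count is an error (orphan
    biomass).
    """
    count = np.asarray(count, dtype=float)
    afdw = np.asarray(fraction_afdw_ug, dtype=float)
    if np.any(count < 0) or np.any(afdw < 0):
        raise ValueError("count and AFDW must be non-negative")
    if np.any((count == 0) & (afdw > 0)):
        raise ValueError("orphan biomass: AFDW > 0 in a fraction with zero count")
    with np.errstate(divide="ignore", invalid="ignore"):
        if params.mode == "individual":
            per_ind = np.where(count > 0, afdw / np.maximum(count, 1), 0.0)
            out = count * edgar_individual_production(per_ind, params)
        else:
            out = edgar_individual_production(afdw, params)
            out = np.where(count > 0, out, 0.0)
    return out if out.ndim else float(out)


def load_group_map(path: str | Path) -> pd.DataFrame:
    """taxon -> (taxon_group, report_group) mapping CSV."""
    df = pd.read_csv(path)
    for col in ("taxon", "report_group"):
        if col not in df.columns:
            raise ValueError(f"group map is missing column {col!r}")
    return df


def sample_production(
    records: pd.DataFrame,
    design: SurveyDesign,
    table: ConversionTable = ConversionTable(),
    params: ProductionParams = ProductionParams(),
    group_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-core biomass and production by report group and sieve class.

    Returns one row per SampleKey x report_group x sieve_mm present in the
    data, with ``biomass_afdw_mg_m2`` and ``production_mg_m2_day`` already
    on areal units (per-core totals divided by the core area; ug -> mg).
    ``group_map`` maps each taxon to a report group; taxa already named
    like a report group map to themselves by default.
    """
    df = records.copy()
    gmap = dict(group_map or {})
    groups = []
    for taxon in df["taxon"].unique():
        g = gmap.get(taxon, taxon if taxon in table.factors else None)
        if g is None:
            raise UnknownTaxonError(
                f"taxon {taxon!r} missing from the group map and not itself a "
                f"known group; known groups: {sorted(table.factors)}"
            )
        groups.append((taxon, g))
    df = df.merge(pd.DataFrame(groups, columns=["taxon", "report_group"]), on="taxon")

    factors = df["report_group"].map(lambda g: table.factor(g))
    afdw_mg = df["wet_weight_mg"].to_numpy(float) * factors.to_numpy(float)
    df["biomass_afdw_mg"] = afdw_mg
    df["production_ug_day"] = fraction_production(
        df["count"].to_numpy(float), afdw_mg * 1000.0, params
    )
    out = (
        df.groupby(KEY_COLUMNS + ["report_group", "sieve_mm"], observed=True)
        .agg(count=("count", "sum"),
             biomass_afdw_mg=("biomass_afdw_mg", "sum"),
             production_ug_day=("production_ug_day", "sum"))
        .reset_index()
    )
    out["biomass_afdw_mg_m2"] = out["biomass_afdw_mg"] / design.core_area_m2
    out["production_mg_m2_day"] = out["production_ug_day"] / 1000.0 / design.core_area_m2
    out = out.drop(columns=["biomass_afdw_mg", "production_ug_day"])
    out.attrs["conversion_table_version"] = table.version
    out.attrs["temperature_C"] = params.T
    out.attrs["mode"] = params.mode
    return out


def per_sample_totals(estimate: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Total biomass and production per core, densified over the design
    (cores with no fauna get zeros)."""
    keys = design.sample_keys()
    totals = (
        estimate.groupby(KEY_COLUMNS, observed=True)[
            ["biomass_afdw_mg_m2", "production_mg_m2_day"]
        ].sum().reset_index()
    )
    out = keys.merge(totals, on=KEY_COLUMNS, how="left").fillna(
        {"biomass_afdw_mg_m2": 0.0, "production_mg_m2_day": 0.0}
    )
    return out


def habitat_summary(estimate: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Mean (+/- SD over cores) biomass and production per estuary x habitat."""
    totals = per_sample_totals(estimate, design)
    g = totals.groupby(["estuary", "habitat"], observed=True)
    out = g.agg(
        biomass_mean=("biomass_afdw_mg_m2", "mean"),
        biomass_sd=("biomass_afdw_mg_m2", "std"),
        production_mean=("production_mg_m2_day", "mean"),
        production_sd=("production_mg_m2_day", "std"),
        n_cores=("biomass_afdw_mg_m2", "size"),
    ).reset_index()
    return out


def size_class_contributions(
    estimate: pd.DataFrame,
    records: pd.DataFrame,
    by: str = "sieve_mm",
) -> pd.DataFrame:
    """Relative abundance / biomass / production shares per estuary x habitat.

    ``by`` is ``"sieve_mm"`` (size-class panels) or ``"report_group"``
    (taxon-group panels).  Shares are fractions in [0, 1] summing to 1
    within each estuary x habitat x quantity; groupings with a zero total
    are reported as NaN (undefined share).
    """
    if by not in ("sieve_mm", "report_group"):
        raise ValueError("by must be 'sieve_mm' or 'report_group'")
    agg = (
        estimate.groupby(["estuary", "habitat", by], observed=True)
        .agg(abundance=("count", "sum"),
             biomass=("biomass_afdw_mg_m2", "sum"),
             production=("production_mg_m2_day", "sum"))
        .reset_index()
    )
    for col in ("abundance", "biomass", "production"):
        total = agg.groupby(["estuary", "habitat"], observed=True)[col].transform("sum")
        agg[f"{col}_share"] = np.where(total > 0, agg[col] / total, np.nan)
    return agg


def annual_pb(
    estimate: pd.DataFrame,
    design: SurveyDesign,
    params: ProductionParams = ProductionParams(),
) -> pd.DataFrame:
    """Annual community P/B per estuary x habitat (y^-1).

    ``days_per_year * mean daily production / mean standing biomass`` over
    the cores of each habitat cell.  Zero production gives P/B = 0; zero
    biomass with positive production is an error.
    """
    summary = habitat_summary(estimate, design)
    bad = summary[(summary["biomass_mean"] == 0) & (summary["production_mean"] > 0)]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"zero mean biomass with positive production at "
                         f"{r['estuary']}/{r['habitat']}")
    with np.errstate(divide="ignore", invalid="ignore"):
        pb = np.where(
            summary["production_mean"] == 0,
            0.0,
            params.days_per_year * summary["production_mean"] / summary["biomass_mean"],
        )
    return summary.assign(pb_annual=pb)[
        ["estuary", "habitat", "biomass_mean", "production_mean", "pb_annual"]
    ]
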