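"""Data model and I/O for nested estuarine macrofauna surveys.

The sampling design is hierarchical: estuaries contain sites, each site
holds both a vegetated (mangrove, ``V``) and an unvegetated (tidal flat,
``NV``) habitat, each site x habitat cell contains plots, and each plot
contains replicate sediment cores.  Habitat is crossed with the spatial
factors; the spatial factors are nested.

Faunal observations are stored tidy: one row per taxon x sieve-class
fraction inside one replicate core.  Zero-count taxa are simply absent
rows; community matrices are densified with explicit zeros on demand.
Mollusk wet weights are shell-free by data-entry contract (no shell-mass
correction is computed here).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: stacked sieve series used to size-fractionate each core (mm mesh)
SIEVE_SERIES: tuple[float, ...] = (1.0, 1.4, 2.0, 2.8, 4.0)

FAUNAL_COLUMNS = [
    "estuary", "site", "habitat", "plot", "replicate",
    "taxon", "sieve_mm", "count", "wet_weight_mg",
]
SEDIMENT_COLUMNS = [
    "estuary", "site", "habitat", "plot",
    "mud_pct", "grain_phi", "tom_pct", "chla", "phaeo", "plant_biomass",
]
#: columns identifying one replicate core
KEY_COLUMNS = ["estuary", "site", "habitat", "plot", "replicate"]
#: columns identifying one plot (sediment sampling unit)
PLOT_COLUMNS = ["estuary", "site", "habitat", "plot"]


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class ValidationError(ValueError):
    """A table violates the survey-design invariants."""


@dataclass(frozen=True)
class SurveyDesign:
    """Balanced nested survey layout plus the corer geometry.

    Defaults mirror a three-estuary mesohaline survey: 3 estuaries x
    2 sites x 2 habitats x 3 plots x 3 replicate cores of 0.0177 m^2
    (15 cm diameter PVC corer), i.e. 108 cores in total.
    """

    estuaries: tuple[str, ...] = ("BEN", "PAE", "VIB")
    sites_per_estuary: int = 2
    habitats: tuple[str, ...] = ("V", "NV")
    plots_per_site_habitat: int = 3
    replicates_per_plot: int = 3
    core_area_m2: float = 0.0177
    sieve_series: tuple[float, ...] = SIEVE_SERIES

    def __post_init__(self) -> None:
        if self.core_area_m2 <= 0:
            raise ValueError("core_area_m2 must be positive")
        for n, what in [
            (self.sites_per_estuary, "sites_per_estuary"),
            (self.plots_per_site_habitat, "plots_per_site_habitat"),
            (self.replicates_per_plot, "replicates_per_plot"),
        ]:
            if n < 1:
                raise ValueError(f"{what} must be >= 1")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.sites_per_estuary))

    @property
    def plots(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1}" for i in range(self.plots_per_site_habitat))

    @property
    def replicates(self) -> tuple[str, ...]:
        return tuple(f"R{i + 1}" for i in range(self.replicates_per_plot))

    @property
    def n_cores(self) -> int:
        return (
            len(self.estuaries) * self.sites_per_estuary * len(self.habitats)
            * self.plots_per_site_habitat * self.replicates_per_plot
        )

    def sample_keys(self) -> pd.DataFrame:
        """Enumerate every core of the full design as one row per SampleKey."""
        rows = itertools.product(
            self.estuaries, self.sites, self.habitats, self.plots, self.replicates
        )
        return pd.DataFrame(rows, columns=KEY_COLUMNS)

    def plot_keys(self) -> pd.DataFrame:
        rows = itertools.product(self.estuaries, self.sites, self.habitats, self.plots)
        return pd.DataFrame(rows, columns=PLOT_COLUMNS)


@dataclass
class BalanceReport:
    """Per-cell core counts and whether the survey is balanced.

    ``cells`` has one row per (estuary, site, habitat, plot) with the
    number of distinct replicate cores observed there.
    """

    n_cores: int
    balanced: bool
    expected_replicates: int
    cells: pd.DataFrame
    problems: list[str] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _check_levels(df: pd.DataFrame, column: str, allowed: Iterable, what: str) -> None:
    allowed = set(allowed)
    bad = set(df[column].unique()) - allowed
    if bad:
        raise ValidationError(
            f"{what}: unknown {column} level(s) {sorted(map(str, bad))}; "
            f"expected one of {sorted(map(str, allowed))}"
        )


def validate_faunal(records: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Validate a tidy faunal table against the design invariants.

    Returns the table with canonical dtypes.  Raises :class:`SchemaError`
    for missing columns and :class:`ValidationError` for bad values,
    naming the first offending row.
    """
    _require_columns(records, FAUNAL_COLUMNS, "faunal")
    df = records.copy()
    for col in KEY_COLUMNS + ["taxon"]:
        df[col] = df[col].astype(str)
    df["sieve_mm"] = pd.to_numeric(df["sieve_mm"])
    df["count"] = pd.to_numeric(df["count"])
    df["wet_weight_mg"] = pd.to_numeric(df["wet_weight_mg"])

    bad = df.index[(df["count"] < 0) | (df["count"] != np.floor(df["count"]))]
    if len(bad):
        raise ValidationError(
            f"faunal row {bad[0]}: count must be a non-negative integer"
        )
    df["count"] = df["count"].astype(int)
    bad = df.index[df["wet_weight_mg"] < 0]
    if len(bad):
        raise ValidationError(f"faunal row {bad[0]}: wet_weight_mg must be >= 0")
    bad = df.index[~df["sieve_mm"].isin(design.sieve_series)]
    if len(bad):
        raise ValidationError(
            f"faunal row {bad[0]}: sieve_mm {df.loc[bad[0], 'sieve_mm']} not in the "
            f"configured sieve series {design.sieve_series}"
        )
    bad = df.index[(df["count"] == 0) & (df["wet_weight_mg"] > 0)]
    if len(bad):
        raise ValidationError(
            f"faunal row {bad[0]}: positive wet weight with zero count (orphan biomass)"
        )
    _check_levels(df, "estuary", design.estuaries, "faunal")
    _check_levels(df, "site", design.sites, "faunal")
    _check_levels(df, "habitat", design.habitats, "faunal")
    _check_levels(df, "plot", design.plots, "faunal")
    _check_levels(df, "replicate", design.replicates, "faunal")
    return df[FAUNAL_COLUMNS]


def validate_sediment(records: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Validate a plot-level sediment table (exactly one record per plot)."""
    _require_columns(records, SEDIMENT_COLUMNS, "sediment")
    df = records.copy()
    for col in PLOT_COLUMNS:
        df[col] = df[col].astype(str)
    for col in SEDIMENT_COLUMNS[4:]:
        df[col] = pd.to_numeric(df[col])
    bad = df.index[(df["mud_pct"] < 0) | (df["mud_pct"] > 100)]
    if len(bad):
        raise ValidationError(f"sediment row {bad[0]}: mud_pct must be within [0, 100]")
    for col in ["tom_pct", "chla", "phaeo", "plant_biomass"]:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValidationError(f"sediment row {bad[0]}: {col} must be >= 0")
    dup = df.duplicated(subset=PLOT_COLUMNS)
    if dup.any():
        raise ValidationError(
            f"sediment row {df.index[dup][0]}: duplicate record for its plot"
        )
    _check_levels(df, "estuary", design.estuaries, "sediment")
    return df[SEDIMENT_COLUMNS]


def load_faunal_table(path: str | Path, design: SurveyDesign) -> pd.DataFrame:
    """Read and validate a tidy faunal CSV (UTF-8, header row mandatory)."""
    return validate_faunal(pd.read_csv(path), design)


def load_sediment_table(path: str | Path, design: SurveyDesign) -> pd.DataFrame:
    return validate_sediment(pd.read_csv(path), design)


def write_faunal_table(records: pd.DataFrame, path: str | Path) -> None:
    records[FAUNAL_COLUMNS].to_csv(path, index=False)


def write_sediment_table(records: pd.DataFrame, path: str | Path) -> None:
    records[SEDIMENT_COLUMNS].to_csv(path, index=False)


def validate_design(records: pd.DataFrame, design: SurveyDesign) -> BalanceReport:
    """Report per-cell core counts and flag imbalance.

    A cell is one (estuary, site, habitat, plot); each must contain
    exactly ``design.replicates_per_plot`` distinct replicate cores for
    the balanced ANOVA engine to apply.  Report only — never raises.
    """
    expected = design.replicates_per_plot
    cells = design.plot_keys()
    if len(records):
        observed = (
            records.groupby(PLOT_COLUMNS, observed=True)["replicate"]
            .nunique()
            .rename("n_replicates")
            .reset_index()
        )
    else:
        observed = pd.DataFrame(columns=PLOT_COLUMNS + ["n_replicates"])
    cells = cells.merge(observed, how="left", on=PLOT_COLUMNS)
    cells["n_replicates"] = (
        pd.to_numeric(cells["n_replicates"]).fillna(0).astype(int)
    )
    cells["balanced"] = cells["n_replicates"] == expected
    problems = [
        f"{r.estuary}/{r.site}/{r.habitat}/{r.plot}: {r.n_replicates} of {expected} cores"
        for r in cells.itertuples()
        if not r.balanced
    ]
    n_cores = int(
        records[KEY_COLUMNS].drop_duplicates().shape[0] if len(records) else 0
    )
    return BalanceReport(
        n_cores=n_cores,
        balanced=not problems and n_cores == design.n_cores,
        expected_replicates=expected,
        cells=cells,
        problems=problems,
    )


def density_per_sample(
    records: pd.DataFrame,
    design: SurveyDesign,
    by: Sequence[str] | None = None,
    per_taxon: bool = False,
) -> pd.DataFrame:
    """Areal density (ind m^-2) per core, densified over the full design.

    Every core of the design appears exactly once (zero for empty cores).
    ``by`` optionally aggregates the per-core densities by a factor subset
    (mean over cores); ``per_taxon`` keeps the taxon breakdown.

    Raises :class:`ValidationError` if a record refers to a core outside
    the design.
    """
    keys = design.sample_keys()
    group_cols = KEY_COLUMNS + (["taxon"] if per_taxon else [])
    if len(records):
        in_design = records.merge(keys, on=KEY_COLUMNS, how="left", indicator=True)
        if (in_design["_merge"] == "left_only").any():
            bad = in_design.loc[in_design["_merge"] == "left_only", KEY_COLUMNS].iloc[0]
            raise ValidationError(f"record for unknown core {tuple(bad)}")
        counts = records.groupby(group_cols, observed=True)["count"].sum().reset_index()
    else:
        counts = pd.DataFrame(columns=group_cols + ["count"])
    if per_taxon:
        taxa = sorted(records["taxon"].unique()) if len(records) else []
        full = keys.merge(pd.DataFrame({"taxon": taxa}), how="cross") if taxa else keys.copy()
        if not taxa:
            full["taxon"] = pd.Series(dtype=str)
    else:
        full = keys
    out = full.merge(counts, on=group_cols, how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    out["density"] = out["count"] / design.core_area_m2
    if by is not None:
        agg_cols = list(by) + (["taxon"] if per_taxon else [])
        out = out.groupby(agg_cols, observed=True)["density"].mean().reset_index()
    return out


def community_matrix(
    records: pd.DataFrame,
    design: SurveyDesign,
    level: str = "core",
    value: str = "count",
) -> pd.DataFrame:
    """Wide samples x taxa matrix, densified with zeros.

    ``level`` is ``"core"`` (one row per replicate core) or ``"plot"``
    (counts summed over the replicates of each plot, the layout used when
    community data must align with plot-level sediment covariates).
    ``value`` is ``"count"`` or ``"density"`` (ind m^-2).
    """
    if level not in ("core", "plot"):
        raise ValueError("level must be 'core' or 'plot'")
    idx_cols = KEY_COLUMNS if level == "core" else PLOT_COLUMNS
    full = design.sample_keys() if level == "core" else design.plot_keys()
    agg = (
        records.groupby(idx_cols + ["taxon"], observed=True)["count"].sum().reset_index()
        if len(records)
        else pd.DataFrame(columns=idx_cols + ["taxon", "count"])
    )
    wide = (
        agg.pivot_table(index=idx_cols, columns="taxon", values="count", fill_value=0)
        if len(agg)
        else pd.DataFrame(index=pd.MultiIndex.from_frame(full))
    )
    wide = wide.reindex(pd.MultiIndex.from_frame(full), fill_value=0)
    wide = wide.astype(float)
    if value == "density":
        area = design.core_area_m2 * (1 if level == "core" else design.replicates_per_plot)
        wide = wide / area
    elif value != "count":
        raise ValueError("value must be 'count' or 'density'")
    wide.columns.name = "taxon"
    return wide
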