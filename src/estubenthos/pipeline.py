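"""End-to-end orchestration: load/simulate -> production -> univariate
ANOVA -> PERMANOVA -> nMDS -> SIMPER -> CCA, with report tables and a
run manifest.

Reports mirror the conventional layout of nested-ANOVA publications:
term order H, E, H x E, S(E), ... with p-values floored at "<0.0001"
and an asterisk marking p < 0.05.  A run is fully determined by its
configuration and seed; re-running writes byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    KEY_COLUMNS,
    SurveyDesign,
    community_matrix,
    density_per_sample,
    load_faunal_table,
    load_sediment_table,
    validate_design,
    write_faunal_table,
    write_sediment_table,
)
from .multivariate import bray_curtis, cca, nmds, permanova, simper, top_taxa
from .production import (
    ConversionTable,
    ProductionParams,
    annual_pb,
    default_group_map,
    per_sample_totals,
    sample_production,
    size_class_contributions,
)
from .simulate import SimulationConfig, field_survey_preset, simulate_survey
from .univariate import cochran_c, core_model_spec, nested_anova, plot_model_spec

SEDIMENT_VARIABLES = ["mud_pct", "grain_phi", "tom_pct", "chla", "phaeo", "plant_biomass"]
DEFAULT_CCA_COVARIATES = ["tom_pct", "chla", "mud_pct", "plant_biomass"]


@dataclass
class RunConfig:
    """One pipeline run: either file inputs or a simulation config.

    ``seed`` drives every permutation and restart procedure and, for
    simulated runs without an explicit simulation config, the generator.
    """

    out_dir: str | Path
    seed: int
    faunal_path: str | Path | None = None
    sediment_path: str | Path | None = None
    conversion_table: ConversionTable = field(default_factory=ConversionTable)
    group_map: dict[str, str] | None = None
    simulation: SimulationConfig | None = None
    design: SurveyDesign = field(default_factory=SurveyDesign)
    params: ProductionParams = field(default_factory=ProductionParams)
    n_perm: int = 9999
    nmds_starts: int = 50
    cca_covariates: tuple[str, ...] = tuple(DEFAULT_CCA_COVARIATES)
    anova_transform: str = "none"
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Build a run configuration from a YAML document.

        Recognised keys mirror the dataclass fields (``out_dir``,
        ``seed``, ``faunal_path``, ``sediment_path``, ``n_perm``,
        ``nmds_starts``, ``cca_covariates``, ``anova_transform``,
        ``temperature``, ``conversion_factors``, ``group_map``);
        keyword overrides win over file values.
        """
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        if "temperature" in doc:
            doc["params"] = ProductionParams(T=float(doc.pop("temperature")))
        if "conversion_factors" in doc:
            doc["conversion_table"] = ConversionTable(
                factors=doc.pop("conversion_factors"), version=str(path)
            )
        if "cca_covariates" in doc:
            doc["cca_covariates"] = tuple(doc["cca_covariates"])
        return cls(**doc)

    def __post_init__(self) -> None:
        has_files = self.faunal_path is not None
        if has_files == (self.simulation is not None):
            if not has_files:
                # neither given: default to the documented preset at this seed
                self.simulation = field_survey_preset(seed=self.seed)
            else:
                raise ValueError("give either input paths or a simulation config, not both")
        if self.simulation is not None:
            self.design = self.simulation.design


def format_p(p: float) -> str:
    """Report-table p formatting: '<0.0001' floor, asterisk at p < 0.05."""
    if not np.isfinite(p):
        return ""
    base = "<0.0001" if p < 1e-4 else f"{p:.2g}"
    return base + ("*" if p < 0.05 else "")


def report_tables(table: pd.DataFrame, p_col: str = "p") -> pd.DataFrame:
    """Format an ANOVA/PERMANOVA table for reporting (does not mutate)."""
    out = table.copy()
    if len(out) == 0:
        return out
    for col in ("SS", "MS", "F", "pseudo_F"):
        if col in out:
            out[col] = out[col].map(lambda v: f"{v:.4g}" if np.isfinite(v) else "")
    if p_col in out:
        out[p_col] = out[p_col].map(format_p)
    return out


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    return obj


def _cochran_groups(data: pd.DataFrame, response: str, cell_cols: list[str]):
    return [g[response].to_numpy() for _, g in data.groupby(cell_cols, observed=True)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write one CSV per report plus manifest.json.

    Returns a dict of in-memory results keyed by stage name.  Any stage
    error propagates with the stage named in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(
            {k: v for k, v in dataclasses.asdict(config).items() if k != "simulation"}
        ),
        "warnings": [],
        "inputs": {},
        "reports": [],
    }
    results: dict = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return _Stage()

    def save(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["reports"].append(name)

    caught: list[warnings.WarningMessage] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with stage("load"):
            if config.simulation is not None:
                faunal, sediment, truth = simulate_survey(config.simulation)
                results["ground_truth"] = truth
                manifest["inputs"]["simulation_seed"] = config.simulation.seed
                write_faunal_table(faunal, out / "simulated_faunal.csv")
                write_sediment_table(sediment, out / "simulated_sediment.csv")
            else:
                faunal = load_faunal_table(config.faunal_path, design)
                sediment = (
                    load_sediment_table(config.sediment_path, design)
                    if config.sediment_path else None
                )
                manifest["inputs"]["faunal"] = {
                    "path": str(config.faunal_path), "sha256": _sha256(config.faunal_path)
                }
                if config.sediment_path:
                    manifest["inputs"]["sediment"] = {
                        "path": str(config.sediment_path),
                        "sha256": _sha256(config.sediment_path),
                    }
            balance = validate_design(faunal, design)
            if not balance.balanced:
                manifest["warnings"].append(
                    f"design imbalance: {'; '.join(balance.problems[:5])}"
                )
            save("balance_report.csv", balance.cells)
            results["balance"] = balance

        with stage("production"):
            gmap = config.group_map or default_group_map(faunal["taxon"].unique())
            estimate = sample_production(
                faunal, design, config.conversion_table, config.params, gmap
            )
            totals = per_sample_totals(estimate, design)
            pb = annual_pb(estimate, design, config.params)
            contrib = pd.concat(
                [size_class_contributions(estimate, faunal, by=b)
                 for b in ("sieve_mm", "report_group")],
                ignore_index=True,
            )
            save("production_estimate.csv", estimate)
            save("production_totals.csv", totals)
            save("pb_ratios.csv", pb)
            save("contributions.csv", contrib)
            results.update(estimate=estimate, totals=totals, pb=pb)

        with stage("anova"):
            dens = density_per_sample(faunal, design)
            core = totals.merge(dens[KEY_COLUMNS + ["density"]], on=KEY_COLUMNS)
            anova_rows = []
            for response, colname in [
                ("density", "density"),
                ("biomass", "biomass_afdw_mg_m2"),
                ("production", "production_mg_m2_day"),
            ]:
                spec = core_model_spec(design, response=colname)
                groups = _cochran_groups(core, colname, [f.name for f in spec.factors])
                coch = cochran_c(groups)
                if coch.heterogeneous:
                    manifest["warnings"].append(
                        f"Cochran's C rejects homogeneity for {response} "
                        f"(C={coch.C:.3f}, p={coch.p_value:.4g}); consider a "
                        "'sqrt' or 'log1p' transform"
                    )
                res = nested_anova(core, spec, transform=config.anova_transform)
                tab = res.table.assign(response=response,
                                       cochran_C=coch.C, cochran_p=coch.p_value)
                anova_rows.append(tab)
                results[f"anova_{response}"] = res
            save("anova_macrofauna.csv", pd.concat(anova_rows, ignore_index=True))

            if sediment is not None:
                sed_rows = []
                for var in SEDIMENT_VARIABLES:
                    spec = plot_model_spec(design, response=var)
                    coch = cochran_c(
                        _cochran_groups(sediment, var, [f.name for f in spec.factors])
                    )
                    res = nested_anova(sediment, spec)
                    sed_rows.append(res.table.assign(response=var, cochran_C=coch.C,
                                                     cochran_p=coch.p_value))
                    results[f"anova_{var}"] = res
                save("anova_sediment.csv", pd.concat(sed_rows, ignore_index=True))

        with stage("permanova"):
            cm = community_matrix(faunal, design, level="core")
            dissim = bray_curtis(cm, transform="sqrt")
            if dissim.attrs["dropped_rows"]:
                manifest["warnings"].append(
                    f"{len(dissim.attrs['dropped_rows'])} empty core(s) excluded "
                    "from the community analyses"
                )
            keys = cm.index.to_frame(index=False).loc[
                [cm.index.get_loc(i) for i in dissim.index]
            ]
            perm = permanova(dissim, keys.reset_index(drop=True),
                             core_model_spec(design), n_perm=config.n_perm,
                             seed=config.seed)
            save("permanova.csv", perm.table)
            results["permanova"] = perm

        with stage("nmds"):
            ord_res = nmds(dissim, k=2, n_starts=config.nmds_starts, seed=config.seed)
            coords = ord_res.coordinates.copy()
            coords.index = pd.MultiIndex.from_tuples(coords.index, names=KEY_COLUMNS)
            save("nmds_coordinates.csv", coords.reset_index())
            manifest["nmds"] = {"stress": ord_res.stress, "converged": ord_res.converged,
                                "n_starts": ord_res.n_starts}
            results["nmds"] = ord_res

        with stage("simper"):
            grouping = [i[KEY_COLUMNS.index("habitat")] for i in cm.loc[dissim.index].index]
            simper_tab = simper(cm.loc[dissim.index], grouping, transform="sqrt")
            save("simper.csv", simper_tab)
            results["simper"] = simper_tab

        with stage("cca"):
            if sediment is not None:
                plot_cm = community_matrix(faunal, design, level="plot")
                taxa5 = top_taxa(plot_cm, n=5)
                Y = plot_cm[taxa5]
                Z = sediment.set_index(
                    ["estuary", "site", "habitat", "plot"]
                )[list(config.cca_covariates)]
                Z = Z.reindex(Y.index)
                cca_res = cca(Y, Z)
                axes = [f"CCA{i + 1}" for i in range(len(cca_res.eigenvalues))]
                summary = pd.DataFrame({
                    "axis": axes,
                    "eigenvalue": cca_res.eigenvalues,
                    "proportion_of_total": cca_res.proportion_total,
                    "proportion_of_constrained": cca_res.proportion_constrained,
                })
                save("cca_summary.csv", summary)
                save("cca_site_scores.csv", cca_res.site_scores.reset_index())
                save("cca_species_scores.csv", cca_res.species_scores.reset_index())
                save("cca_biplot_scores.csv", cca_res.biplot_scores.reset_index())
                results["cca"] = cca_res
                manifest["cca"] = {
                    "top_taxa": taxa5,
                    "total_inertia": cca_res.total_inertia,
                    "constrained_inertia": cca_res.constrained_inertia,
                }

    manifest["warnings"].extend(str(w.message) for w in caught)
    if config.plots:
        _write_plots(results, out, manifest)
    manifest["conversion_table_version"] = config.conversion_table.version
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _write_plots(results: dict, out: Path, manifest: dict) -> None:
    """Optional convenience figures; never part of acceptance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "nmds" in results:
        coords = results["nmds"].coordinates
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=12)
        ax.set_xlabel("MDS1")
        ax.set_ylabel("MDS2")
        ax.set_title(f"nMDS (stress = {results['nmds'].stress:.3f})")
        fig.tight_layout()
        fig.savefig(out / "nmds.png", dpi=120)
        plt.close(fig)
    if "cca" in results:
        res = results["cca"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(res.site_scores.iloc[:, 0], res.site_scores.iloc[:, 1], s=10,
                   alpha=0.6)
        for name, row in res.biplot_scores.iterrows():
            ax.annotate(name, (row.iloc[0], row.iloc[1]), color="green")
            ax.arrow(0, 0, row.iloc[0], row.iloc[1], color="green", lw=0.8)
        ax.set_xlabel("CCA1")
        ax.set_ylabel("CCA2")
        fig.tight_layout()
        fig.savefig(out / "cca.png", dpi=120)
        plt.close(fig)
    manifest["plots"] = True
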