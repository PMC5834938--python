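"""Nested mixed-model ANOVA of density, biomass and production, plus the
plot-level sediment variables, each preceded by Cochran's C.

Writes results/analysis/anova_{macrofauna,sediment}.csv with EMS-chosen
denominators and report-style p formatting.
"""

from pathlib import Path

import pandas as pd

from estubenthos import core_model_spec, plot_model_spec, nested_anova, cochran_c
from estubenthos.core_data import KEY_COLUMNS, density_per_sample
from estubenthos.pipeline import SEDIMENT_VARIABLES, report_tables
from estubenthos.production import default_group_map, per_sample_totals, sample_production
from estubenthos.simulate import field_survey_preset, simulate_survey

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    config = field_survey_preset(seed=1)
    design = config.design
    faunal, sediment, _ = simulate_survey(config)

    totals = per_sample_totals(
        sample_production(faunal, design,
                          group_map=default_group_map(faunal["taxon"].unique())),
        design,
    )
    core = totals.merge(density_per_sample(faunal, design)[KEY_COLUMNS + ["density"]],
                        on=KEY_COLUMNS)

    frames = []
    for response, col in [("density", "density"), ("biomass", "biomass_afdw_mg_m2"),
                          ("production", "production_mg_m2_day")]:
        spec = core_model_spec(design, response=col)
        cells = [g[col].to_numpy() for _, g in
                 core.groupby([f.name for f in spec.factors], observed=True)]
        coch = cochran_c(cells)
        res = nested_anova(core, spec)
        frames.append(res.table.assign(response=response, cochran_C=coch.C,
                                       cochran_p=coch.p_value))
        sig = [t for t, p in zip(res.table.term, res.table.p) if p < 0.05]
        print(f"{response}: Cochran C={coch.C:.3f} (p={coch.p_value:.3g}); "
              f"significant terms at alpha=0.05: {sig or 'none'}")
    pd.concat(frames).pipe(report_tables).to_csv(OUT / "anova_macrofauna.csv", index=False)

    sed_frames = []
    for var in SEDIMENT_VARIABLES:
        spec = plot_model_spec(design, response=var)
        res = nested_anova(sediment, spec)
        sed_frames.append(res.table.assign(response=var))
    pd.concat(sed_frames).pipe(report_tables).to_csv(OUT / "anova_sediment.csv", index=False)
    print(f"\nwrote {OUT / 'anova_macrofauna.csv'} and {OUT / 'anova_sediment.csv'}")


if __name__ == "__main__":
    main()
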