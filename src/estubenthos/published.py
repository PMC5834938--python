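"""Published summary tables from the three-estuary survey this package
re-analyses, used as desk-check inputs.

The original study reported balanced mixed nested ANOVA and PERMANOVA
tables (mean squares per term) for the 3 estuaries x 2 sites x 2
habitats x 3 plots x 3 replicate-cores design.  Only the printed mean
squares are stored here; the F and pseudo-F ratios are *recomputed* by
the EMS denominator logic and compared against the printed ratios —
a zero-data validation of the mixed-model machinery.

Term symbols: H habitat (fixed), E estuary, S site, P plot (random).
"""

from __future__ import annotations

#: macrofaunal ANOVA mean squares (density / biomass / secondary
#: production responses); 108 cores, residual df 72
MACROFAUNA_ANOVA_MS: dict[str, dict[str, float]] = {
    "density": {
        "H": 311266.70, "E": 689817.25, "H × E": 1230614.84, "S(E)": 35368.39,
        "P(S(E))": 25774.72, "H × S(E)": 53413.02, "H × P(S(E))": 37327.63,
        "Residual": 6255.48,
    },
    "biomass": {
        "H": 0.20, "E": 0.32, "H × E": 0.54, "S(E)": 0.07,
        "P(S(E))": 0.02, "H × S(E)": 0.03, "H × P(S(E))": 0.03, "Residual": 0.01,
    },
    "production": {
        "H": 6.43, "E": 8.95, "H × E": 15.29, "S(E)": 1.60,
        "P(S(E))": 0.54, "H × S(E)": 0.58, "H × P(S(E))": 0.59, "Residual": 0.33,
    },
}

#: published F ratios for the density ANOVA (printed to 3 decimals)
MACROFAUNA_DENSITY_F: dict[str, float] = {
    "H": 0.253, "E": 19.504, "H × E": 23.040, "S(E)": 1.372,
    "P(S(E))": 4.120, "H × S(E)": 1.431, "H × P(S(E))": 5.967,
}

#: sediment-properties ANOVA (plot-level responses; residual df 24)
SEDIMENT_ANOVA_MS: dict[str, dict[str, float]] = {
    "grain_phi": {
        "H": 0.64, "E": 5.11, "H × E": 0.95, "S(E)": 1.47, "H × S(E)": 1.49,
        "Residual": 0.24,
    },
    "mud_pct": {
        "H": 710.88, "E": 4190.30, "H × E": 392.01, "S(E)": 886.16,
        "H × S(E)": 843.80, "Residual": 101.75,
    },
    "tom_pct": {
        "H": 1244.64, "E": 283.85, "H × E": 279.85, "S(E)": 177.85,
        "H × S(E)": 50.62, "Residual": 15.46,
    },
}

SEDIMENT_GRAIN_F: dict[str, float] = {
    "H": 0.680, "E": 3.474, "H × E": 0.635, "S(E)": 6.115, "H × S(E)": 6.204,
}

#: community PERMANOVA mean squares (Bray-Curtis on sqrt abundances)
PERMANOVA_MS: dict[str, float] = {
    "H": 34861.0, "E": 24587.0, "S(E)": 4771.7, "H × E": 18394.0,
    "P(S(E))": 1577.5, "H × S(E)": 4213.5, "H × P(S(E))": 1625.0,
    "Residual": 653.61,
}

PERMANOVA_PSEUDO_F: dict[str, float] = {
    "H": 1.895, "E": 5.153, "S(E)": 3.025, "H × E": 4.366,
    "P(S(E))": 2.414, "H × S(E)": 2.593, "H × P(S(E))": 2.486,
}

#: degrees of freedom of the core design, in the published term order
MACROFAUNA_DF: dict[str, int] = {
    "H": 1, "E": 2, "H × E": 2, "S(E)": 3, "P(S(E))": 12,
    "H × S(E)": 3, "H × P(S(E))": 12, "Residual": 72,
}
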