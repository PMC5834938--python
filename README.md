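# estubenthos

Analysis of benthic macrofauna from nested estuarine surveys: vegetated
(mangrove) versus unvegetated (tidal flat) habitats sampled across
estuaries, sites, plots and replicate cores. The package covers the full
chain used in quantitative soft-bottom community ecology:

- **Secondary production** from sieve-fractionated biomass. Wet weights
  per taxon × sieve class (1, 1.4, 2, 2.8, 4 mm) are converted to
  ash-free dry weight (AFDW) and daily production is estimated with the
  general allometric model *P* = 0.0049 · *B*^0.80 · *T*^0.89 (*P* in
  µg day⁻¹ per individual, *B* the mean individual AFDW in µg, *T* the
  water temperature in °C, standardised at 23.5 °C), applied per
  individual within each taxon × sieve fraction and summed per core.
  Annual turnover is *P/B* = 365 · mean production / mean biomass.
- **Balanced mixed nested ANOVA** with expected-mean-squares (EMS)
  denominator selection (Cornfield–Tukey rules, restricted model) for
  the design *habitat* (fixed) × *estuary* / *site(estuary)* /
  *plot(site(estuary))* (random), preceded by Cochran's C homogeneity
  test. Sums of squares are exact orthogonal projections.
- **Community statistics**: Bray–Curtis dissimilarity on square-root
  abundances, nested PERMANOVA sharing the EMS denominator map
  (permutation of residuals under a reduced model), non-metric MDS
  (SMACOF with monotone regression, Kruskal stress-1), SIMPER, and
  canonical correspondence analysis of the dominant taxa against
  sediment covariates (TOM, chlorophyll-a, mud content, plant biomass).
- **A survey simulator** with known ground truth (negative-binomial
  counts, log-scale random effects per nesting level, multinomial sieve
  allocation, allometric individual masses) so every stage is testable
  and calibratable without field data.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
documented simulation preset and write their tables under
`results/analysis/`. The zero-data desk check reconstructs every
published F ratio from printed mean squares using only the EMS
denominator map:

```sh
$ python analysis/01_desk_check_published_tables.py
Density ANOVA F ratios recomputed from printed mean squares:
       term         MS denominator      F
          E  689817.25        S(E) 19.504
          H  311266.70       H × E  0.253
      H × E 1230614.84    H × S(E) 23.040
       S(E)   35368.39     P(S(E))  1.372
   H × S(E)   53413.02 H × P(S(E))  1.431
    P(S(E))   25774.72    Residual  4.120
H × P(S(E))   37327.63    Residual  5.967
```

Each F is the printed mean square divided by the mean square of the
term whose EMS matches the numerator's expectation under the null —
e.g. the estuary term is tested against site-within-estuary, not the
residual. The simulated survey then flows through the same machinery:

```sh
$ python analysis/02_simulate_survey.py
simulated 108 cores (balanced: True), 37 taxa, 15548 individuals
...
BEN     NV       30653.0  22972.0     # mean, SD density (ind m^-2)

$ python analysis/05_community_structure.py
PERMANOVA (9999 permutations): significant terms: ['E', 'H × E', 'S(E)']
nMDS stress = 0.234 (converged: True, 21 starts)
taxa driving the V/NV dissimilarity (average dissimilarity 0.62):
          taxon  contribution_pct
Kalliapseudidae              16.5
    Oligochaeta              10.8
```

The tidal flats of the BEN-analogue estuary carry a dense tanaid bloom
(~3 × 10⁴ ind m⁻²), the habitat × estuary interaction dominates — the
same qualitative structure the statistics are designed to resolve.

A CLI wraps the pipeline end to end:

```sh
estubenthos run-all --seed 1 --out-dir results/run1            # simulate + analyse
estubenthos run-all --faunal my_faunal.csv --sediment my_sed.csv --seed 7
```

Input CSVs are tidy: one row per taxon × sieve × core
(`estuary,site,habitat,plot,replicate,taxon,sieve_mm,count,wet_weight_mg`)
and one sediment row per plot. Mollusk wet weights are shell-free by
convention.

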