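# Methods

## The survey model

The sampling design is hierarchical and balanced: estuaries (3) contain
sites (2, hundreds of metres apart), each site holds an adjacent
vegetated (mangrove, V) and unvegetated (tidal flat, NV) habitat,
each site × habitat cell contains plots (3, tens of metres apart), and
each plot contains replicate cores (3, ~1 m apart; 0.0177 m², 15 cm
diameter, 10 cm deep) — 108 cores. Habitat is a fixed factor crossed
with the spatial factors; estuary, site and plot are random and nested.
Sediment covariates exist once per plot (36 rows), so sediment ANOVAs
use plots as the residual stratum.

## Secondary production

Individuals are sorted through stacked sieves (1, 1.4, 2, 2.8, 4 mm),
so each taxon × sieve fraction approximates one body-size class. Wet
weight is converted to AFDW by taxon-group factors, and daily
production follows the allometric model P = a·B^b·T^c with a = 0.0049,
b = 0.80, c = 0.89 (P µg day⁻¹, B µg AFDW, T °C).

Two readings of B are possible for a fraction holding N individuals of
total mass M. The default evaluates the model at the mean individual
mass and multiplies by abundance, N·P(M/N) — the size-class method,
consistent with sieving individuals into near-uniform size classes.
The alternative, P(M), evaluates the whole fraction at once; because
B^0.8 is concave the two differ by exactly N^(1−b) = N^0.2, so the
choice matters (a factor ~2.5 at N = 100). The whole-fraction mode is
available behind `ProductionParams(mode="whole_fraction")` and the mode
is echoed in every output.

Temperature is standardised at 23.5 °C (the narrow range measured
across these tropical estuaries during sampling); per-run temperatures
are accepted via `ProductionParams(T=...)`. Annualisation uses 365
days. Areal units: per-core totals are divided by 0.0177 m²; biomass is
reported in mg AFDW m⁻², production in mg m⁻² day⁻¹, P/B in y⁻¹.

The default AFDW/wet-weight factors (Polychaeta 0.155, Oligochaeta
0.150, crustaceans 0.175, shell-free Mollusca 0.120, Others 0.150) are
round central values from the standard compilations for soft-bottom
macrofauna; they are deliberately editable (CSV-loadable) and the table
version string is attached to every production output, because absolute
biomass/production reproduction is tolerance-limited by whichever
factor set a study used.

## Mixed nested ANOVA

For balanced mixed models the correct F denominator of each term is the
mean square whose expectation equals the numerator's EMS under the
null. EMS are derived symbolically by the Cornfield–Tukey algorithm
under the restricted mixed-model convention (interactions of a fixed
with a random factor carry the summation constraint — the convention of
the ecological ANOVA literature). For the core design this yields
H→H×E, E→S(E), H×E→H×S(E), S(E)→P(S(E)), H×S(E)→H×P(S(E)),
P(S(E))→residual, H×P(S(E))→residual; for the plot-level sediment
design, S(E) and H×S(E) test against the residual. A design with no
single matching denominator raises an explicit quasi-F error rather
than approximating.

Sums of squares are computed by orthogonal effect projectors obtained
by Möbius inversion of the cell-mean averaging operators over the
subscript-set lattice; in balanced designs these are exact, mutually
orthogonal, and sum to the total SS. The engine refuses unbalanced data
(no Type I/III approximations) — that exactness is the point. Degrees
of freedom are projector traces. Method-of-moments variance components
are solved from the EMS linear system; the raw solution is reported
alongside the conventional zero-truncated one.

Cochran's C (max group variance over the sum, across the 36 design
cells) precedes each ANOVA. Its p-value uses the union bound on the
Beta law of a single variance ratio, p = min(1, k·P(Beta(ν/2,
(k−1)ν/2) > C)); the bound is exact whenever the critical value exceeds
1/2, which holds at α = 0.05 for these group counts, and simulation
confirms the 5% null rate. On rejection the engine warns and offers
sqrt / log1p transforms but never transforms silently — which responses
were transformed in any given published table is generally unstated, so
silent transformation would fake reproducibility.

p-values below 10⁻⁴ print as "<0.0001" and p < 0.05 carries an
asterisk in report tables, mirroring the field's table conventions.

## PERMANOVA

The Gower-centred inner-product matrix G of the Bray–Curtis distances
is partitioned with the same effect projectors: SS_term = tr(P_term G),
so the partition is exact and, with Euclidean distances, every pseudo-F
equals the univariate F (a cross-module invariant under test).
Denominators reuse the EMS map. Partial (Type III) SS semantics are
moot here: the balanced design makes sequential and partial SS
identical (asserted by the orthogonality test).

Significance uses permutation of residuals under a reduced model
(Freedman–Lane): for each term, all other modelled effects are swept
from G, the residual matrix is permuted whole (rows and columns), and
both the numerator and denominator mean squares are recomputed;
p = (b+1)/(m+1) with 9999 permutations by default and a mandatory,
logged seed. Unit-level restricted permutations are impractical for
upper-level terms here (few exchangeable units), which is exactly why
the residual-permutation family is the standard default in this kind of
software; its type-I error is verified by simulation in the test suite.
All-zero community rows have no Bray–Curtis distance and are excluded
with a warning, never imputed.

## nMDS, SIMPER, CCA

nMDS minimises Kruskal stress-1 by SMACOF majorisation with monotone
(isotonic) regression, best of 50 random starts plus one metric
(classical scaling) start, convergence at stress change < 10⁻⁶ or 500
iterations. A collapsed configuration counts as degenerate (infinite
stress) rather than a perfect fit. Stress is non-increasing across
iterations by construction (property-tested).

SIMPER decomposes the average between-group Bray–Curtis dissimilarity
additively over taxa by averaging the per-pair, per-taxon terms
|x_ik − x_jk| / Σ_k(x_ik + x_jk) over all cross-group pairs, on the
same square-root scale as the dissimilarity.

CCA chi-square-standardises the plot-level community table (community
rows are replicate sums so they align one-to-one with the plot-level
sediment covariates), regresses it on weight-standardised covariates
with row-mass weights, and eigen-decomposes the fitted values. Total
inertia equals the table's chi-square statistic over its grand total
and splits exactly into constrained plus residual inertia. Because
"variation explained" is ambiguous, each axis reports its eigenvalue as
a fraction of *both* total and constrained inertia. The analysis uses
the five most abundant taxa (summed density, ties broken
lexicographically and logged); collinear covariates are dropped with a
warning. Eigenvalues are cross-checked against scikit-bio's independent
CCA in the tests.

## The simulator

`simulate_survey` draws, from a single mandatory seed: Gaussian random
effects on the log scale at the estuary, site and plot levels (the plot
effect attaches to the (estuary, site, plot) unit shared by both
habitats, i.e. the model's P(S(E)) stratum); negative-binomial counts
per taxon × core around μ_taxon,habitat,estuary × exp(effects)
(negative binomial because field macrofauna are overdispersed —
reported SDs routinely exceed means); a multinomial split of each count
over the five sieve classes, independent of abundance; individual wet
masses log-normal around an allometric midpoint (coef · sieve³ mg), so
mean individual mass rises with sieve class; and plot-level sediment
covariates whose means differ by habitat and which are linearly coupled
to the shared plot effect, giving constrained ordination a recoverable
signal.

The documented preset (`field_survey_preset`) emulates the three-estuary
mesohaline survey it is modelled on: 37 taxa; vegetated habitats
dominated by Oligochaeta and Capitellidae; a Kalliapseudidae bloom on
one estuary's flats driving that cell to ~3 × 10⁴ ind m⁻² (mean
individual ~0.3 mg AFDW); an urbanised-estuary analogue with
Spionidae/Capitellidae flats; sparse flats in the third; low-density,
large-bodied bivalves and crabs carrying most vegetated biomass.
Variance components σ_estuary = 0.15, σ_site = 0.25, σ_plot = 0.30
(log scale) and NB size 2 reproduce the field-typical coefficient of
variation of cell means (~0.5–0.7). These choices were fixed once
against the published marginal summaries and are not tuning knobs.

What the simulator does **not** emulate: coordinate-based spatial
autocorrelation (nesting levels are the only spatial structure),
taxon-to-taxon interactions beyond shared random effects, temporal
variation, and count-dependent sieve allocation. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the declared generative model, not the field realism of
any particular dataset.

## Problem sizes and numerical choices

The test suite calibrates the three null tests by simulation at sizes
chosen to give tight binomial bands while keeping the suite quick:
2000 vectorised normal surveys for the ANOVA F tests, 10,000 trials for
Cochran's C, 250 null communities × 99 permutations for PERMANOVA (all
3σ bands); parameter recovery uses 500 surveys of the full 108-core
design. Analysis scripts use 9999 permutations (the conventional
figure) and 20–50 nMDS starts. Ties, dropped rows, Cochran rejections
and seeds are logged in the run manifest; reports are byte-identical
under a repeated configuration + seed.

## Known limitations

- Balanced designs only; unbalanced data are rejected, not
  approximated.
- The Edgar-type allometric model with a fixed temperature yields
  *relative* production for comparing habitats/estuaries sampled under
  similar conditions, not absolute annual production (no seasonality,
  no cohort structure, no length–weight regressions).
- Absolute biomass/production depends on the AFDW conversion-factor
  table; published values are generally reproducible only up to that
  table's uncertainty.
- The Freedman–Lane p-values are asymptotically, not exactly, valid for
  upper-level random terms; the permutation-count discreteness floor is
  1/(m+1).
- Whether colonial/fragmented annelid counts were corrected upstream is
  a data-entry question; counts are stored as given.
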