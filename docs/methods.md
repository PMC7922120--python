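# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Toxicity indices

**aAPTLc.** For a vineyard's spray regime the area-related acute pesticide
contact toxicity loading is

    aAPTLc = s · Σ (amount_g_per_ha / LD50_µg_per_bee) · (half_life_days / ln 2)

summed over every (application, active ingredient) pair. The amount applied
is the product dose (g/ha at field level) times the ingredient's mass
concentration. The hazard-quotient term (amount / honeybee contact LD50)
weights each application by acute contact toxicity; the half-life over ln 2
is the mean environmental residence time in days, so an ingredient with
half-life exactly ln 2 days contributes its bare hazard quotient. The
scaling factor s defaults to 1e-4; it is a display convention and provably
cannot change any rank-based downstream result (a test asserts the AICc
ranking is invariant to rescaling the index). ln 2 is always computed,
never typed as a decimal.

Missing toxicology is table-driven: an ingredient with a blank LD50 or
half-life is skipped and reported per vineyard in an exclusion list.
Potassium bicarbonate is the one shipped exception — its half-life is
routinely absent from reference databases, and the package substitutes a
configurable default of 7 days rather than dropping one of the most
frequently applied organic products.

**Categorical *T. pyri* rating.** Every applied-ingredient occurrence
contributes the numeric value of its harm class for *Typhlodromus pyri* —
harmless 0.4 (< 40% reduction of beneficial capacity), slightly harmful 0.8
(40–80%), harmful 1.0 (> 80%) — and the rating is the per-vineyard sum. The
sum is over occurrences, not distinct ingredients: a season with ~22
ingredient-applications lands in the low teens, the magnitude the index is
designed to report. When an ingredient has several published test outcomes
the reference table stores the worst class; unknown classes are excluded
and reported. Whether ingredients missing LD50/half-life should also leave
the rating is undefined behaviour in the source protocol; the package
excludes only unknown harm classes and reports both exclusion lists so the
analyst can reconcile them.

**Application counts.** The total counts distinct application dates —
several products sprayed on one date are one application — while
per-category counts count product applications. The total can therefore be
far below the category sum for regimes that tank-mix.

## Field samples

Mite densities are counts per measured total leaf area × 100 (individuals
per 100 cm²); the two eriophyoid species are merged into one taxon (their
densities are near zero individually) by summation, idempotently. The
spider-mite taxon is carried through even when identically zero, so absence
is an observable output rather than a missing column. Pollen densities
divide transect counts by the counted fraction of the 19 × 19 mm tape
square (3.61 cm²); the counted fraction is an explicit input because the
transect width depends on the microscope's field of view, and inventing an
optics constant would hide a real measurement parameter.
Amaranthaceae/Caryophyllaceae and Moraceae/Urticaceae are merged (they are
morphologically indistinguishable as grains); AP/NAP/NA pass through
merges. The unidentifiable NA category is included in total density by
default but excluded from community composition analyses (configurable).
Reported percentages round to 2 decimals; internal values keep full
precision.

## Landscape metrics

Patches arrive pre-classified into 18 habitat classes — 14 analysed
(hedgerow, solitary trees, tree rows, woodland; fallow, grassland, grass
strip; vineyard, arable crops; orchard, scrub, garden, ruderal vegetation,
reed) and 4 excluded from analysis (artificial, ponds/rivers, roads,
yards). Composition percentages are grouped area over the full circle area
by default: the excluded classes physically occupy the circle, so
percentages remain interpretable as shares of the 500-m circle. A flag
(`analyzed_only`) switches both the composition denominator and SHDI to the
14 analysed classes; neither convention is asserted to be the published
one, both are implemented and logged. SHDI is −Σ p ln p (nats) over class
area shares; zero-area classes contribute nothing. The woody-SNH distance
is the minimum edge-to-edge polygon distance in a projected metric system;
with no woody patch in the circle the distance is missing (never 0), and a
precomputed distance column is accepted verbatim when geometries are
unavailable. The 500-m radius is data, not code: circles arrive
pre-delimited by `circle_id`.

## Model selection

Responses are transformed to log10(y + 1) — densities are non-negative
with occasional zeros, and the +1 keeps zero at zero. Models are additive
Gaussian GLMs with identity link, i.e. maximum-likelihood least squares on
the transformed response, with treatment contrasts (first level of the
closed set as reference; the reference choice moves signs, not fits).

Screening: predictor pairs with |Pearson r| ≥ 0.5 (any indicator contrast
for categoricals) may not share a model; VIF_j = 1/(1 − R²_j) from
auxiliary regressions flags terms above 5 for removal; constant columns are
flagged rather than correlated. Every exclusion decision is logged at INFO.

AICc uses k = number of regression coefficients + 1 for the residual
variance (the convention under which standard AICc implementations agree),

    AICc = −2 logL + 2k + 2k(k+1)/(n − k − 1),

with the Gaussian ML log likelihood logL = −(n/2)(ln(2π σ̂²) + 1),
σ̂² = RSS/n. Δi = AICc_i − min AICc; the parsimonious set is {Δi ≤ 2}.
Exact AICc ties break by fewer parameters, then lexicographic term order,
and are logged. Adjusted R² uses the OLS convention
1 − (1 − R²)(n − 1)/(n − p − 1) with p slope coefficients.

The candidate set is declared, not discovered: the published analysis this
package generalises never listed its 42 models, so the shipped
configuration is the package's own reproduction surface — `date` forced
into every non-null model (every published selection retained it), a pool
of 9 field and landscape predictors, 5 exclusion pairs (the toxicity
loading, application count and summer vegetation cover all track
management), and at most 2 non-date terms. That enumerates exactly 42
candidates: null + date + 9 singles + 31 exclusion-respecting pairs. An
explicit model list can replace the generator and is validated against the
exclusions. Cross-response predictors (other taxa's transformed densities)
are ordinary additive columns — no simultaneity modelling. A mixed-model
variant with vineyard pairs as a random effect is deliberately out of
scope: with 16 circles of 2 paired vineyards, pair-level variance estimates
collapse to zero and hit boundary problems, so the paired design is carried
in the data model but modelled with plain GLMs.

The least-squares solve is a closed-form numpy solve; statsmodels OLS
serves as the independent cross-check in the tests (coefficients to 1e-8,
likelihood to 1e-8), never as the implementation.

## Association statistics

Spearman's rho is the Pearson correlation of average ranks with a
t-distribution (n − 2 df) p-value; missing pairs drop listwise; constant
vectors return missing with a warning rather than a spurious coefficient.

The pollen-community ordination is non-metric MDS minimising Kruskal
stress-1 (0–1 scale). The dissimilarity defaults to Bray–Curtis — the
conventional choice for abundance data; the source protocol does not name
one — with Euclidean and Jaccard as configurable alternatives, and no
transformation or standardisation is applied by default (also unstated in
the protocol; both decisions are logged here). Optimisation runs SMACOF
with monotone regression from a classical-scaling (PCoA) start plus seeded
random restarts (8 by default), keeping the lowest stress; scores are
centred, and results are deterministic given the seed. Non-convergence
returns the best-so-far solution flagged as such. Stress above 0.2 triggers
an interpretation warning in the summary.

Trait fitting follows the envfit convention: continuous traits get the
least-squares direction in score space and its squared correlation;
categorical traits get level centroids and a between-group r²
(1 − SS_within/SS_total). Significance comes from permuting trait rows —
999 permutations by default, seeded — with p = (1 + #{r²_perm ≥ r²_obs}) /
(1 + N). There is no Python equivalent of vegan's envfit in the supported
environment, so this component is implemented here and its null behaviour
is property-tested (permutation p-values approximately uniform).

The seasonal split is fixed by the sampling calendar: dates 1–2 (early
May, early June) are spring, dates 3–5 (July–August) are summer.

## Synthetic-data generator

The generator emulates the study design end to end: 16 landscape circles,
each with one organic and one integrated vineyard (32 total), cover-crop
types cycled near-balanced across the three levels, and five sampling
dates. Its defaults are the study conditions:

- **Spray regimes.** Category application counts are truncated-normal
  draws with organic means sulfur 9.19 ± 1.6, copper 8.88 ± 1.84,
  potassium bicarbonate 4.44 ± 2.76, acaricide 0.25 ± 0.45 and zero
  synthetic fungicides/insecticides; integrated means synthetic fungicide
  5.79 ± 2.58, sulfur 4.13 ± 1.84, copper 1.25 ± 0.83, insecticide
  0.25 ± 0.45, acaricide 0.38 ± 0.5 and zero potassium bicarbonate.
  Products applied in the same spray round share dates, so distinct-date
  totals land near 9–10 (organic) vs 6–7 (integrated). The reference
  tables carry plausible published-range toxicology, one ingredient with a
  deliberately missing LD50 and one with a missing half-life (potassium
  bicarbonate) to exercise both missing-value paths. Copper's persistence
  makes the organic loading several-fold the integrated one by
  construction — the direction, and roughly the magnitude, of the
  motivating field data, though not calibrated to reproduce its exact
  means.
- **Densities.** Effects are injected on the log10(y + 1) scale — the
  scale the GLMs fit — so recovery experiments have an exact generating
  model. Phytoseiid baselines decline from 0.91 (≈ 7 mites/100 cm²) at
  date 1 to 0.50 (≈ 2.2) at date 5; organic management −0.20, spontaneous
  cover +0.20, vineyard share +0.010/%, SNH share −0.010/% (composition
  terms centred at their generated means of ~30% so the linear predictor
  stays in the positive-density regime); residual SD 0.15. Tydeoid and
  pollen responses follow analogous profiles, pollen peaking at date 2
  (early June). Densities back-transform, convert to integer counts given
  a drawn leaf area (25 leaves of 100–200 cm²), and are re-measured by the
  pipeline — so count quantisation is part of the simulated measurement.
  Eriophyoid counts are additionally zero-inflated (p = 0.5) and split
  between the two species; spider mites are identically zero.
- **Landscape.** Class shares are Dirichlet-style draws with the total
  SNH share uniform in 10–55% and the vineyard share drawn independently
  (rescaled only when a circle would overflow), so the two composition
  predictors are not collinear by construction; patch areas sum exactly to
  π·500² m². Woody-SNH distances are lognormal draws supplied as a
  precomputed column; rectangle geometries support the distance tests.

What the generator does **not** emulate: spatial autocorrelation between
paired vineyards, mite dispersal between patches and vineyards, observation
error in leaf-area measurement, within-season weather, or real product
labels. Passing recovery tests therefore show the inference machinery is
correct under the stated generative model, not that the field conclusions
are reproduced.

## Experiment sizes and numerics

The recovery experiment replicates 200 seeded studies (32 vineyards × 5
dates each) and asks whether the generating phytoseiid term set (date +
management + cover crop + vineyard share + SNH share) sits in the Δi ≤ 2
set; candidates are enumerated up to 4 non-date terms for this experiment
so the generating model is inside the candidate set (under the default
2-term cap the question would be unanswerable by construction). The null
experiment (100 replicates, all effects zeroed) asks how often the null
model stays in the parsimonious set. The toxicity fuzz check runs 1000
random regimes of up to 5 applications against a brute-force per-term
evaluation at 1e-12 relative tolerance. These sizes are the package's
documented experiment conditions and are what `scripts/acceptance.py`
reruns.

Degenerate inputs are errors, not silent zeros: non-positive leaf areas,
counted fractions outside (0, 1], negative doses, unknown habitat classes
and rank-deficient designs (aliased terms are named) all raise. Constant
predictors and traits are flagged/skipped with warnings. All stochastic
components (generator, NMDS restarts, permutations) consume explicit seeds
and are deterministic given them.

## Known limitations

- The candidate-set configuration is a documented reconstruction, not the
  published list; selection results depend on it.
- The Gaussian GLM on log10(y + 1) is the protocol's model; it is not ideal
  for the near-zero, zero-inflated eriophyoid response, and the generator
  reproduces that tension faithfully (eriophyoid recovery is weaker by
  design and not asserted).
- NMDS stress depends on restarts; pathological matrices may return
  best-so-far solutions flagged unconverged.
- The deposit adapter maps expected spreadsheet column spellings; mapping a
  real deposit may require extending `DEPOSIT_COLUMN_MAP`, the one
  component intended to change on inspection.
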