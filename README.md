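# vinemites

Analysis pipeline for paired-vineyard field studies of predatory mites
(Phytoseiidae, Tydeidae), phytophagous mites (Eriophyidae, Tetranychidae)
and leaf-surface pollen, and how their densities respond to local pesticide
management, inter-row cover crops and landscape composition.

The package is aimed at agroecologists working with vineyard spray records,
leaf-wash mite counts, sticky-tape pollen counts and habitat maps. It
covers:

- **Pesticide toxicity indices.** The area-related acute pesticide contact
  toxicity loading for a vineyard's spray regime,

  aAPTLc = 1e-4 × Σᵢ (amountᵢ [g/ha] / LD50ᵢ [µg/bee]) × (half-lifeᵢ [d] / ln 2),

  summed over every application of every active ingredient (amount = product
  dose × ingredient concentration; LD50 is the honeybee contact value), plus
  a categorical toxicity rating for the predatory mite *Typhlodromus pyri*
  that sums a fixed harm-class scale (harmless 0.4, slightly harmful 0.8,
  harmful 1.0) over all applied-ingredient occurrences.
- **Field-sample normalisation.** Leaf-wash counts to mites per 100 cm² leaf
  area, eriophyoid species merging, phytoseiid species shares, and
  sticky-tape transect counts extrapolated to pollen grains per cm².
- **Landscape metrics.** Habitat patches inside 500-m circles aggregated to
  % woody semi-natural habitat (SNH), % total SNH, % vineyards and % total
  agriculture, Shannon landscape diversity (SHDI = −Σ p ln p), and the
  minimum edge-to-edge distance to woody SNHs (shapely geometries or
  precomputed).
- **Multi-model AICc inference.** Gaussian GLMs (identity link) on
  log10(y+1) densities over a declared candidate set (42 additive models
  under the shipped configuration), collinearity (|r| ≥ 0.5) and VIF (> 5)
  screening, AICc = −2logL + 2k + 2k(k+1)/(n−k−1) ranking and the Δi ≤ 2
  parsimonious set — organised statsmodels-style
  (`DensityModelSelection(...).fit()` → `SelectionResults` with `summary()`).
- **Association statistics.** Spearman correlations, Bray–Curtis NMDS
  ordination of pollen communities split into spring (dates 1–2) and summer
  (dates 3–5), with envfit-style permutation-tested trait fitting.
- **Synthetic studies.** A seeded generator producing complete paired
  studies (16 organic/integrated pairs, 3 cover-crop types, 5 sampling
  dates, management-specific spray regimes, 10–55% SNH landscapes) with
  known ground truth for recovery experiments.

## Worked example

```python
import vinemites as vm

study = vm.generate_study(seed=7)                       # synthetic paired study
tox = vm.compute_toxicity(study.spray, study.ingredients, study.products)
print(tox.merge(study.metadata, on="vineyard_id")
         .groupby("management")[["aaptlc", "tpyri_rating"]].mean().round(2))
```

```
             aaptlc  tpyri_rating
management
integrated     5.56         11.61
organic       23.58         12.80
```

Organic regimes carry roughly twice the rating occurrences and a several-fold
higher toxicity loading — the copper- and sulfur-based products permitted in
organic viticulture are applied far more often than the synthetic fungicides
they replace.

```python
from vinemites.experiments import study_analysis_table

table = study_analysis_table(study)                     # one row per vineyard-date
results = vm.DensityModelSelection(table, "phytoseiid").fit()
print(results.ranking.head(3)[["model", "aicc", "delta_i", "adj_r2"]].round(2))
```

```
                                      model    aicc  delta_i  adj_r2
          date + management + pct_total_snh -118.11     0.00    0.65
              date + aaptlc + pct_total_snh -108.72     9.39    0.62
date + n_applications_total + pct_total_snh  -87.42    30.69    0.57
```

The shipped 42-model set caps candidates at two non-date terms, so the best
model picks the two strongest generating effects: predatory-mite density
declines over the season, is higher under integrated management, and falls
with the surrounding share of semi-natural habitat. (The recovery
experiments in `vinemites.experiments` widen the cap to four terms so the
full generating model is enumerable.) The full pipeline (`vinemites run --config pipeline.yml`, or
`vinemites.pipeline.run_pipeline`) chains toxicity → densities → landscape →
model selection → correlations → seasonal NMDS and writes a results bundle
with a run log.

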