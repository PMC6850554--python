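# middencache

Analysis pipeline for cache-size variation in larder-hoarding red
squirrels. Red squirrels (*Tamiasciurus*) store conifer cones for the
winter in a central midden, depositing them into excavated "pits" in the
scale pile or soil; the number of pits dug during the caching season is
a field-practical proxy for cache volume. On a sky-island mountain at
the hot edge of the species' range, the question is which of the
candidate drivers — microclimate, topographic relief, forest structure,
food availability, or the resident squirrel's sex — actually moves cache
size.

The package implements the full analysis as a tested library plus
numbered driver scripts, and ships a synthetic-study generator that
reproduces the field design (40 monitored middens, six visits each,
~30% attrition, a 15 male / 11 female / 2 unknown retained sex pattern,
block-correlated covariates) with known ground-truth effects, so every
stage of the pipeline is verifiable end to end without the field data.

## Methods at a glance

- **Microclimate correction** — midden readings are compared against
  fixed reference series (summit weather station for air temperature and
  humidity, buried data logger for soil/pit/scale-pile temperatures)
  taken at the same time: corrected value = midden − baseline, averaged
  over visits. A *pit cooling effect* (pit − air temperature) captures
  how much cooler the cache interior is than ambient air.
- **Circular aspect** — slope aspect θ is screened for uniformity with a
  Kuiper test (V = D⁺ + D⁻, rotation invariant) and folded onto the
  northeast–southwest axis: bearings in [45°, 225°] pass through, the
  rest reflect as (90° − θ) mod 360°, giving a linear covariate where 45
  = NE-facing and 225 = SW-facing.
- **Covariate reduction** — iterative PCA within biotic and abiotic
  groups: z-scored variables, eigenvalue-scaled PC1–PC2 loadings, a
  per-variable dissimilarity score (mean Euclidean distance to the other
  loading vectors); among significantly Pearson-correlated pairs the
  less dissimilar member is deleted, one per round, then the surviving
  variables are pooled and the loop repeats.
- **Model selection** — Gaussian identity-link GLMs of log pit count
  (null with a frozen random covariate, all one- and two-covariate
  additive models), ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with
  k counting coefficients plus the residual variance. Akaike weights
  w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2), and a bootstrap selection frequency
  π_i — the share of 10,000 row-resamples on which model i has the
  lowest AICc.
- **Sex-stratified inference** — Welch t-tests (Satterthwaite df) on pit
  counts and aspect by sex, the percent male/female difference on raw
  counts, and per-sex OLS of raw pit counts on linearized aspect.
  Moran's I (row-standardized inverse-distance weights, permutation p)
  screens cone-count data for the spatial clustering that would
  invalidate conifer density as a local food-availability proxy.

## Worked example

Run the numbered drivers in order (each writes its tables under
`results/`):

```
python analysis/01_simulate_study.py
python analysis/02_preprocess.py
python analysis/03_reduce_covariates.py
python analysis/04_model_selection.py
python analysis/05_sex_differences.py
```

The simulation draws the study design and the preprocessing screens it:

```
generated 40 middens; 28 retained after attrition ({'male': 15, 'female': 11, 'unknown': 2})
aspect uniformity: Kuiper V = 0.170, p > 0.15
log pit counts: Shapiro-Wilk W = 0.961, p = 0.370 (normal enough)
```

so the middens cover all slope aspects evenly and the log-transformed
response passes the normality screen. The reduction collapses the 19
correlated candidates to a small dissimilar set (14 eliminations, each
logged with its justifying correlation), and model selection on the four
principal covariates ranks the candidate set:

```
                        model_label  k  delta_aicc  waicc    pi
          Aspect + Density of Trees  4         0.0 0.8569 0.847
                             Aspect  3         4.5 0.0919 0.057
          Aspect + Soil Temperature  4         7.0 0.0265 0.057
           Air Temperature + Aspect  4         7.2 0.0239 0.031
                   ...
best model: Aspect + Density of Trees
  wAICc = 0.8569, pi = 0.847 (B = 10000, redraws = 0)
  deviance explained = 59.9%
```

The generating model (aspect + tree density) tops both the Akaike-weight
and bootstrap-frequency rankings; on this replicate it explains ~60% of
the log pit-count variation (the across-replicate mean sits at the
generator's calibrated 44%). The sex analysis on the same replicate
finds males caching more than females (Welch t = 2.23, df = 22.5,
p = 0.036; +78% pits) and a negative aspect slope in both sexes, i.e.
larger caches on the cooler NE-facing slopes.

The same pipeline runs on a field CSV via the CLI
(`middencache report --input middens.csv --schema-map map.json`), with a
configurable column mapping; `middencache --help` lists the subcommands
(`generate`, `preprocess`, `reduce`, `select`, `sexdiff`, `report`).

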