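# Methods

This note records the statistical model behind the pipeline, the
choices made where the procedure was genuinely open, and what the
synthetic generator does and does not emulate.

## The generative model

Pit counts are drawn on the natural-log scale:

    N_i = max(1, round(exp(η_i + ε_i))),
    η_i = β₀ + β_a·aspect_lin_i + β_t·trees_i + log(ρ_sex)·1[male_i],
    ε_i ~ Normal(0, σ²)

Counts are rounded and floored at 1 because the downstream analysis log
transforms the response and the field protocol never records a zero-pit
occupied midden; flooring keeps the transform total. The realized η_i
are carried in the dataset's ground truth for recovery testing.

Defaults (one per-field choice, fixed once):

| parameter | default | meaning |
|---|---|---|
| `n_middens` | 40 | monitored middens |
| `attrition_rate` | 0.3 | fraction lost to resident death/migration; exactly ⌊0.3·40⌋ = 12 flagged |
| `sex_probs` | (15, 11, 2)/28 | retained-sample sex composition |
| `beta_aspect` | −0.006 /deg | log pits per degree of NE→SW linearized aspect |
| `beta_trees` | −0.0013 /(ind/ha) | log pits per tree/ha (tree density ~ N(500, 160²)) |
| `sex_effect` | 1.47 | multiplicative male/female cache ratio |
| `noise_sd` | 0.37 | residual SD of log pits |
| `intercept` | 5.0 | log pits at covariate zero (≈40 pits mid-slope for a female) |
| `covariate_correlation` | 0.6 | within-group latent-factor loading² |
| `n_visits` | 6 | visits per midden |

The effect sizes are calibrated jointly so that, across replicate
studies, the aspect+trees model explains ≈44% of log pit-count
variation, its median AICc advantage over the aspect-only model is
≈3.4, males cache ≈47% more than females, and retained counts span
roughly 15–170 pits — the scales the field study reports. The
calibration uses ~200-replicate Monte Carlo estimates; smaller batches
of 50 replicates wander visibly (the selection-frequency ranking of the
best model has replicate-to-replicate SD ≈ 0.27).

Covariate structure: each of the nine biotic (vegetation + food) and
seven latent-driven abiotic variables loads on one shared standard-normal
factor per group with loading √0.6, plus independent noise, then is
placed on its natural unit scale. This reproduces the "many mutually
correlated measurements of few underlying gradients" situation the
reduction step exists for, but deliberately makes group members
*symmetric*: on synthetic data the reduction keeps one representative
per latent block, which is not always the same variable the field
analysis kept (e.g. live-conifer density may survive instead of total
tree density). The model-selection driver therefore fits the four
principal covariates the field analysis retained (aspect, tree density,
air and soil temperature) rather than whatever representative the
reduction happened to keep. Snow cover is generated monotone in
linearized aspect plus noise (no snow-physics model); sex placement is
apportioned deterministically (largest remainder) within the retained
and excluded strata so the realized composition matches the design
exactly, then randomly permuted across middens. An optional switch
places males preferentially on NE slopes (an observed confound in the
field data); it is off by default because it is a nuisance association,
not a generative assumption.

What the generator does **not** emulate: sex×aspect interaction (both
sexes share β_a, so per-sex synthetic slopes are both ≈ −0.2 to −0.35
pits/degree, unlike the field observation of a steep female and flat
male slope); spatially explicit midden coordinates; observation error in
pit counting; year-to-year variation. Passing tests therefore establish
that the pipeline recovers known effects under the study's design and
noise levels — not that the field data satisfy the model.

## Microclimate correction

Visit readings are matched to the nearest baseline record within a
configurable tolerance (±30 min default; the field protocol says only
"taken at the same time") — station series for air temperature and
humidity, buried-logger series for soil, pit and scale-pile
temperatures. Corrected value = reading − baseline; per-midden output is
the mean over visits with the contributing visit count reported. Middens
with fewer than the design's six usable visits are kept and flagged, not
imputed. The correction is exactly invariant to any signal added to both
the visits and the baseline, which is the property that makes corrected
means comparable between middens measured on different days.

Pit cooling is computed literally as pit − air temperature (negative
when the pit is cooler). The verbal convention "how much cooler" would
flip the sign; a `sign=` switch exists because either convention is
defensible and only the sign of its regression coefficient changes.

## Aspect handling

Bearings are folded across the 45°–225° line by θ ↦ (90° − θ) mod 360°
for θ outside [45°, 225°]. This is the unique reflection onto that
semicircle preserving each bearing's angular distance to the NE–SW axis;
it is idempotent and two-to-one except on the axis itself (properties
under test). The axis bearing is configurable (`--axis-bearing`).
Uniformity is screened with the Kuiper statistic V = D⁺ + D⁻ on
bearings/360, with Stephens' small-sample-corrected asymptotic p-value;
because that series is sharp only in the tail, non-rejections are
reported as the conventional bracket "p > 0.15". Empirical type-I at
n=28 and α=0.05 measures 0.05 ± 0.01.

## Covariate reduction

The published procedure names PCA "dissimilarity" without defining it.
Here: variables are z-scored (ddof 1); loadings on the first two
components are scaled by √eigenvalue (correlation-biplot convention, so
a loading is the variable–component correlation); a variable's
dissimilarity is the mean Euclidean distance between its PC1–PC2 loading
vector and every other variable's (an angular-separation metric is
available behind `metric="angular"`). "Correlated" is operationalized as
a two-sided Pearson test at α=0.05. One deletion per round — the
largest-|r| significant pair is examined and its less dissimilar member
deleted (ties: larger |r| first, then label order; equal dissimilarity
deletes the alphabetically later name) — then the PCA is recomputed.
Batch deletion would also satisfy the published wording; single-step was
chosen because it is order-reproducible and each deletion is justified
against the current structure. Groups are reduced separately, then the
pooled survivors are reduced once more. Termination is guaranteed: every
round deletes exactly one variable or stops. False deletions on
independent data run at the pairwise type-I rate (α per tested pair),
which across the ~8 pairs of a small candidate set means roughly one in
three fully-independent datasets still loses a variable — a property of
the published procedure itself, not of this implementation.

## Model selection

Gaussian identity-link GLMs on log pit counts are OLS fits; the
log-likelihood uses the ML variance RSS/n, and k = coefficients + 1
counts the variance, matching the published table's Df column (3 for
one-covariate, 4 for two-covariate models). The null model uses one
standard-normal covariate per midden, drawn once from the run seed and
frozen, so the null row is reproducible; whether the original analysis
redrew it per resample is unknowable, and freezing makes the bootstrap
null travel with its rows. Interaction models exist behind a flag but
are excluded from the default set (the published analysis discarded them
for poor performance; no numeric threshold was given, so exclusion is
unconditional). AICc requires n − k − 1 > 0 and is a hard error below
that. π_i uses a nonparametric bootstrap (n rows with replacement;
`with_replacement=False` subsamples 80% instead, since "random
resamples" admits either reading). Resamples producing any
rank-deficient fit are redrawn and counted; with continuous covariates
redraws are essentially never observed. Ties in AICc resolve to fewer
parameters, then label order — identically in the full-data ranking and
inside the bootstrap. The bootstrap is vectorized over resamples (batched
normal equations), so B=10,000 over 11 models at n=28 takes about a
second.

Selection variability is real at this sample size: across replicate
synthetic studies at the calibrated effects, the generating model tops
the π ranking in ≈79% of replicates (mean π ≈ 0.56), with the aspect-only
and aspect+noise-covariate models taking the rest. This mirrors the
study's own situation — a best-model π of ≈0.6 means the selected model
is expected to lose the top rank in a substantial fraction of
re-collections of the data.

## Sex-stratified inference

Welch t-tests with Satterthwaite df (the published fractional df fixes
the unequal-variance variant); percent difference is
(mean_m − mean_f)/mean_f × 100 on raw counts; per-sex aspect regressions
use raw pit counts by default — the published female slope (−0.359
pits/degree over a 180° range) is only plausible on the raw-count scale —
with `response="log_pits"` available. Unknown-sex middens are excluded
from all sex-stratified operations and included everywhere else.
Moran's I uses row-standardized inverse-distance weights (the most
common default; the published choice is unstated), expectation
−1/(n−1), and a permutation p (999 default; the permutation null is
exact in level). Observed and expected I agree with R's `ape::Moran.I`
to 1e-9 on shared weights.

## Numerical and degenerate-input policy

Constant columns are hard errors in PCA and the normality screen;
rank-deficient designs are hard errors in full-data fits and redraws in
the bootstrap; log of a count below 1, bearings outside [0, 360), AICc
with n ≤ k+1, zero-variance Moran inputs and empty sex classes all
raise rather than warn. Seeds: every stochastic operation takes an
explicit seed; the generator's dataset and its visit series derive from
`seed` and `seed + 1`.

## Problem sizes

The test suite and the acceptance script run the bootstrap at B=10,000
on single studies and B=300–500 inside replicate loops (π's Monte-Carlo
SE at B=500 is ≈0.022, far below the ≈0.27 between-replicate SD it is
compared against); replicate counts are 40–200 per property; type-I
calibrations use 500–1000 simulations with 199 permutations per Moran
test. These sizes put every Monte-Carlo standard error well inside the
asserted tolerance while keeping a full run in tens of seconds.

## Known limitations

- The reduction's retained set on synthetic data identifies latent
  blocks, not the field analysis's specific variable names (see above).
- The asymptotic Kuiper p-value is approximate for mid-range p; only
  tail decisions and the "p > 0.15" bracket are relied on.
- The generator's lognormal-rounded counts are overdispersed relative to
  Poisson but carry no midden-level covariate measurement error.
- Percent sex difference on raw counts is right-skewed at n=15/11; its
  single-study value scatters widely (±20 points) around the generating
  47%.
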