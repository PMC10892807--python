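# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

A trait table is one row per plant with design columns
(`plant_id, plot_id, treatment, year`) followed by 22 trait columns
(vegetative morphology, flowering phenology, floral morphology, anthocyanin
pigmentation), each with units and a value class (continuous or count) in
the trait catalog. Invariants enforced on construction: finite non-negative
values, integral counts (floats accepted within 10⁻⁶, tolerating "3.0"),
unique plant ids within a treatment-year, and each plot belonging to exactly
one treatment. Missing values are empty cells (or `NA`) on disk and are
never coerced to zero. `flower_longevity = male_phase + female_phase` is
checked as a warning rather than an error because the three durations are
separately observed quantities in the source tables; leaf traits are stored
as per-plant means without leaf-level replicates. Continuous values are
serialized with `repr` and parsed with round-trip float precision, so
write→read is lossless and repeated writes are byte-identical.

## Synthetic-data generator

The generator is the package's stand-in for the unpublished raw data: it
emulates the field design (6 plots × treatment, 108 morphology plants and a
36-plant floral subset per treatment-year, floral plants spread round-robin
across plots so the subset stays plot-balanced).

Marginals per treatment-year cell:

- **Continuous traits** — moment-matched Gamma with the cell's target mean
  and total SD. Gamma (not Normal) keeps values positive and mirrors the
  right-skew typical of size and duration traits; parameterization fails
  loudly when SD ≥ 10 × mean.
- **Count traits** (branch, flower, labellum-stripe numbers) — Poisson at
  the cell mean, truncated at the lower bound.
- **Flower longevity** is generated as male + female phase, preserving the
  data-model identity; its published cell means equal the phase sums to
  ±0.001 d, so calibration is unaffected.

Published "mean ± x" values are interpreted as mean ± SE (the conventional
reading for such tables; switchable to SD via `se_is_se`). The SE→SD
conversion always uses the published group sizes (36 floral, 108
morphology), never the simulated cohort size, so inflating the cohort for
calibration checks leaves the per-plant distribution unchanged.

**Plot effects.** Each (cell, trait, plot) gets a mean-zero Normal shift
with SD = `plot_sd_fraction` × total SD; the within-plot SD is reduced so
the total is preserved. The study reports no variance decomposition, so the
default `plot_sd_fraction = 0.2` (4 % of variance between plots) is a
modest, configurable choice. The fraction scales SD, not variance: at 0.5,
between-plot variance is one third of within-plot variance.

**Cross-trait dependence.** Independent by default. An optional Gaussian
copula (any PSD correlation matrix over a trait subset) produces correlated
fixtures for the multivariate stages; real trait correlations are unknown,
so none are baked in.

**Vegetative morphology placeholders.** The study reports morphology only
as figures plus percent changes, so those traits carry reconstructed cell
means: a realistic control-2017 baseline (plant height 50 cm, basal
diameter 6 mm, 6 branches, crown width 30 cm, leaf area 20 cm², leaf
9 × 3.5 cm) from which the four cell means are solved to reproduce the
reported warming and year percent changes exactly; SEs assume a 15 %
coefficient of variation. These specs are flagged `calibrated=False` and are
excluded from calibration checks. `null_params` copies control cells over
warming cells, giving an exact no-treatment-effect model for type-I-error
studies.

What passing tests on this generator show — and what they do not: they
verify the pipeline's arithmetic, calibration and error rates under known
marginals with plot structure; they cannot validate the study's actual
trait correlations, non-Gamma tail behaviour, or measurement error, none of
which are published.

## AHP engine

Weights are the normalized principal right eigenvector of each positive
reciprocal judgment matrix, computed by power iteration to relative
tolerance 10⁻¹² (positive matrices are primitive, so convergence to the
Perron vector is guaranteed); λ_max is estimated as the mean of the
component-wise ratios (M·w)ᵢ/wᵢ, exact at convergence and numerically
stable. CI = (λ_max − n)/(n − 1), CR = CI/RI(n); orders 1–2 are consistent
by construction. The RI table (0.52, 0.89, 1.12, 1.26, 1.36, 1.41, 1.46 for
n = 3–9, extended to n = 15) is the variant standard in the AHP literature
this analysis follows; a 50 000-replicate Monte-Carlo estimate over the
full reciprocal 1–9 scale reproduces it to better than 0.05 at every order
(the 0.58-based variant fails that check at n = 3). Matrices failing
CR < 0.100 abort weight synthesis unless explicitly allowed.

The source's appendix judgment matrices are not public. The shipped
defaults are therefore reconstructions, built to satisfy the consistency
gate and the qualitative structure the study states: flowering criteria
dominate, plant morphology is the lightest criterion, and pedicel length,
floral color, flower longevity and flowering duration carry the largest
global weights (0.207/0.110/0.204/0.204 under the defaults). All matrices
are overridable, and reported weights should be read as "a consistent
weighting with the published ordering", not as the original expert
judgments.

The hierarchy has 15 indices: the 14 labelled PCA indicators plus vexillum
length. The source counts 15 indices but labels only 14 in its screening
figure (and references an undefined "FH"); vexillum length was chosen as
the fifteenth because it is a measured floral trait with a significant
warming response. Floral color is realized as the relative anthocyanin
content of the vexillum — the banner petal that displays the color.

**Grading.** Default rubric: quintile breakpoints (20/40/60/80th
percentiles) of the pooled cohort — both treatments and years — so grades
measure relative standing within the study and are invariant to rescaling
any index. Fixed external breakpoints are supported for cross-study
comparability. All default directions are higher-is-better (longer pedicels,
spurs and flowering, more flowers, stronger color all raise ornamental
value); the direction flag reverses grading where a user's catalog says
otherwise. A 1–5 grade scale is used; the published score range (≈2.5–2.9)
is consistent with it. Plants missing some indices are scored on weights
renormalized over the present indices (flagged per plant) rather than
imputed, keeping scores interpretable; morphology-only plants are therefore
scored on the morphology indices alone.

## Effect statistics

`percent_change` is signed, positive meaning a decrease relative to the
reference, matching the study's wording ("shortening by 9.70 %"); values
are kept at full precision and rounded half-up to two decimals only for
display. Year effects pool the two treatment cells of each year by
unweighted mean (cells have equal n by design, so weighting is moot) with
2017 as reference. Group tests are Welch's unequal-variance *t* with
Welch–Satterthwaite degrees of freedom — chosen over Student's *t* because
group variances are not assumed equal, and over the original GLMM/Tukey
machinery, which is out of scope. Two published year-effect percentages
(male phase 19.12 %, flower longevity 21.68 %) are not reproducible from
the published cell means under any simple pooling, and the published 2018
score decline (4.67 %) is inconsistent with its own group means (which give
14.67 %); the package reports values computed from means and leaves those
numbers aside.

## PCA

Eigen-decomposition of the correlation matrix of complete-case standardized
data (ddof = 1), components ordered by eigenvalue, each loading column's
sign fixed so its largest-magnitude entry is positive, scores = Z·V.
Implemented directly rather than delegated so the contract (ordering, sign,
variance shares summing to 100 %) is explicit; the test suite cross-checks
against an SVD oracle at 10⁻⁸. The published variance shares (16.7/13.8 %
in 2017, 20.0/13.4 % in 2018) depend on the unpublished correlation
structure and are not calibration targets.

## PLS path modelling

Classic iterative algorithm: mode-A outer weights (indicator–proxy
covariances), inner proxies by the path scheme (regression weights from
predecessors, correlation weights from successors; centroid and factorial
schemes available), latent scores rescaled to unit variance each pass, sign
fixed so each block's summed indicator correlation is non-negative.
Convergence when the largest absolute outer-weight change falls below 10⁻⁷
(hard error with the last delta after 300 iterations). Inner coefficients
are then OLS of each endogenous latent on its predecessors — standardized
path coefficients, with R² per endogenous latent. Collinear predecessor
sets (condition number > 10¹⁰, or coefficients beyond the 10³ cap) raise
rather than report nonsense. With single-indicator blocks the iteration is
a no-op and the engine is exactly standardized path analysis — the central
oracle in the tests.

The default structural model follows the study's diagram: a binary warming
indicator feeding three trait blocks (each proxied in the study by its
first principal component; the engine supports full multi-indicator blocks)
feeding the score. Because the source is ambiguous about whether flowering
forms one block or two, both variants ship
(`two-flowering-blocks` default, `one-flowering-block` alternative).
Bootstrap: case-resampling of plants, percentile 95 % CIs, significance =
CI excludes zero, failed replicates redrawn up to 10× the replicate count;
the original application's settings are unreported, so defaults
(500 replicates, path scheme) are configurable. Multivariate stages use
listwise deletion; with the default design this means the floral subset
(72 plants per year).

## Pipeline and reproducibility

`run_pipeline` executes simulate → score → effects → pca → sem; a stage
failure (e.g. a judgment matrix failing the CR gate) halts downstream
stages with the stage named in the error. One seed drives everything:
per-stage substreams are spawned from a single `SeedSequence`, floats in
artifacts are rounded to 10 decimals before writing, and `report.json`
records the seed and a SHA-256 digest per artifact, so identical
configurations produce byte-identical outputs. PCA and the path model run
per year, as in the source analysis.

## Problem sizes in the checks

Calibration is verified on 10 000-plant cells (all four cells, every
calibrated trait within 3 published SEs) with plot effects off, isolating
the marginal calibration from plot-level noise. Type-I error: 200 null
replicates at the real design size, pooled over every trait × year Welch
test, with plot effects off — plant-level tests assume independence, and
with six plots per treatment any intraclass correlation makes them
anticonservative by design of the experiment, not by a defect of the test.
The nominal-rate band is 5 % ± 2 %. Path-coefficient recovery uses
n = 5000 (β = 0.5 within ±0.05); bootstrap null significance uses 200
experiments × 200 replicates at n = 200 with an accepted band of 1–10 %
around the nominal 5 %, allowing for percentile-interval small-sample
distortion. The Monte-Carlo RI check uses 50 000 random matrices per order
with batched power iteration.

## Known limitations

- Default AHP matrices and the grading rubric are reconstructions; absolute
  score levels are not comparable to the source's printed scores, only the
  relative structure (direction and approximate magnitude of group
  differences) is.
- The generator draws independent traits by default; PCA/PLS results on
  default synthetic data reflect that near-independence plus the
  treatment/year mean structure, not real trait covariation.
- GLMM fitting, type-III Wald tests and Tukey-adjusted marginal means are
  deliberately out of scope; Welch tests and percent changes are the
  supported contrasts.
- No plotting; tables and JSON reports are the outputs.
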