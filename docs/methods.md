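# Methods

This note documents the models implemented in `rootpatch`, their
assumptions, the defaults of the synthetic-transect generator, and the
numerical choices that were genuinely open.

## Sampling design

One 9 m transect per grassland site, 30 plots/soil cores at 0.3 m
spacing, 28 sites split 10/9/9 over three regions. Vegetation is a
plot × species percent-cover matrix (covers may sum past 100 % under
layered canopies); herbivores are per-core counts identified to family;
soil cores carry fresh/dry weights and root dry mass; two extra cores
per site give water-holding capacity. Site management is summarized by
the land-use intensity index `LUI = F/F_R + M/M_R + G/G_R`, each
component scaled by its regional mean so a site managed exactly at the
regional average scores 3.0.

## Community metrics

* Shannon diversity uses the standard negative sum
  `H' = −Σ pᵢ ln pᵢ` with `pᵢ` the share of summed plant cover;
  bare soil is not part of the denominator.
* The community-weighted mean of a trait is the cover-weighted mean
  over species **with a value for that trait**, with weights
  renormalized over those species. A plot is omitted for a trait when
  the covered fraction falls below the threshold (default 0.8), applied
  per trait per plot, so one plot can enter the SLA analysis yet be
  missing for root density.
* Soil water content and water-holding capacity are percentages of dry
  weight, `(wet − dry)/dry × 100`, so values above 100 % are legal.
* z-standardization (sample sd, n−1) is computed once over the pooled
  analysis dataset — all retained blocks of all sites — so that slopes
  on different predictors share a scale. Standardizing within site
  would change the question being asked (within- vs between-site
  contrast); the pooled scope matches single-slope-per-predictor
  reporting.

## Spatial statistics

* **Distance classes.** The Sturges rule is applied to the number of
  plot pairs, `K = ⌈1 + log₂ n(n−1)/2⌉` (435 pairs → K = 10; applying
  it to n = 30 would give 6 and a different design). Classes of width
  `w = (d_max − d_min)/K` are centered at `d_min + k·w`, the first
  truncated at 0; for the standard transect this yields 0–0.72,
  0.72–1.56, …, 7.44–8.28 m, and the three longest pairs (8.4 m and
  8.7 m apart) fall beyond the last class and are excluded.
* **Mantel correlogram.** For each class the statistic is the Pearson
  correlation between the dissimilarity matrix and the binary
  class-membership matrix over all included pairs, **negated** so that
  a positive coefficient means within-class similarity. Significance
  is a two-sided permutation test (default 999 simultaneous
  row/column permutations, `p = (1 + exceedances)/(n_perm + 1)`), with
  the progressive Holm correction: classes are tested in order of
  increasing distance and the k-th evaluated class' p is multiplied by
  k. A pattern is *autocorrelated* if any class survives correction,
  *patchy* if additionally the first (or second) class is significant
  and positive while some later class coefficient is ≤ 0.
* Species composition uses Bray-Curtis on raw percent covers; trait
  composition uses Euclidean distance on the per-site CWM matrix with
  columns standardized first (otherwise LDMC, two orders of magnitude
  larger than leaf density, would own the metric); herbivore counts use
  the univariate Euclidean distance (absolute count difference), the
  natural single-variable specialization.
* **Moran's I** uses inverse-distance weights `w_ij = 1/d_ij`
  (row-unstandardized), permutation significance measured two-sided
  around the null expectation −1/(n−1). Sites whose counts show
  significant Moran's I at α = 0.05 are excluded from the count models,
  since a mixed model with iid block errors is misspecified there.

## Count models

Per-core counts are heavily zero-inflated, so counts are summed and
predictors averaged over blocks of three adjacent cores
(30 cores → 10 blocks). A block inherits a missing predictor value if
any constituent plot is omitted for it, and drops out of that
predictor's model only. Bare-soil cover is log-transformed (ln(x+1))
before standardization.

One Poisson GLMM per z-scored predictor:

    y_bi ~ Poisson(μ_bi),  log μ_bi = α_region(i) + β₁ z_bi + u_i,
    u_i ~ N(0, σ²_site)

Region enters as a fixed factor (too few levels for a random effect);
for reporting, the three region intercepts are averaged. The site
random intercept is integrated out with a one-dimensional Laplace
approximation per site: the posterior mode of each `u_i` is found by a
vectorized Newton solve, giving the marginal log-likelihood
`Σ(y η̂ − e^η̂) − Σ b̂²/2σ² − ½ Σ log(1 + σ² Σ_j μ̂_ij)`, maximized over
(β, log σ) with L-BFGS-B from an IRLS start. An adaptive 10-node
Gauss–Hermite mode is provided as a cross-check; on typical fits the
two agree in the slope to < 5 × 10⁻³ and in log-likelihood to < 0.05.
With σ² pinned at zero the model collapses exactly to a Poisson GLM
solved by IRLS, which is the test suite's bridge to the independent
statsmodels oracle.

* **Effect test.** The likelihood-ratio χ² against the model without
  the predictor; its p-value comes from a parametric bootstrap
  (default 500 draws): responses are simulated from the *reduced*
  model's fitted parameters, both models refit (warm-started), and the
  observed LRT referred to the bootstrap distribution,
  `p = (1 + #{LRT* ≥ LRT})/(n_done + 1)`; failed refits are dropped
  and counted.
* **Conditional R²** follows the fixed-plus-random over total variance
  decomposition on the latent log scale,
  `(σ²_f + σ²_site)/(σ²_f + σ²_site + σ²_ε)` with `σ²_f` the variance
  of the fixed linear predictor and the observation-level variance
  approximated as `ln(1 + 1/λ̄)` (λ̄ = mean fitted count); the trigamma
  variant is available behind a flag. The lognormal form is the
  default because it is the more widely reported variant for Poisson
  responses at small λ̄.
* Predictors are ranked by |slope| descending, ties broken by name.

Mantel coefficients of spatially structured parameters are regressed on
LUI, water-holding capacity and distance-class center (plus all pairwise
interactions) in a Gaussian LMM with a site random intercept
(statsmodels `MixedLM`, ML). Predictors are standardized internally so
the interaction columns are well conditioned (retention decisions are
invariant to this). Backward selection removes the largest-p term above
α = 0.05, interactions before the main effects they contain
(marginality); term p-values come from the parametric bootstrap, or the
asymptotic χ²₁ LRT when speed matters (`p_method="lrt"` — note the
asymptotic version is anti-conservative at ~14 clusters, which the test
suite accounts for). A fuller model that cannot be fitted numerically
cannot defend its extra term, which is then dropped.

Site-level summaries (total abundance, count variance, mean richness)
are regressed on LUI by OLS, reporting R² and the F-test p.

## Synthetic-transect generator

The generator's defaults *are* the study conditions; the test suite and
acceptance script run at those values.

* **Vegetation.** Each site samples 30 species from a 190-species pool.
  Three broad "matrix" species keep every plot vegetated; every other
  species receives a Poisson number of Gaussian patch kernels (sd =
  `patch_length_scale`, default 1 m — the scale of individual root
  systems) centered along the transect, with the patch rate scaled
  inversely with patch size so expected occupancy stays roughly
  constant. Per-plot totals are rescaled to a lognormal matched to mean
  95.6 %, sd 31.1 %. This yields Bray-Curtis similarity that decays
  with plot separation and correlograms that classify as patchy.
  The first-class Mantel coefficient rises with `patch_length_scale`
  through the sub-metre range and flattens (slightly declines) beyond
  ~1 m, where very large patches turn patchiness into a smooth
  gradient spread across all distance classes — the stochastic-increase
  property is therefore checked by rank correlation, not strict
  monotonicity of means.
* **Traits.** Lognormal per trait, moment-matched to community-level
  means/sds (SLA 20.1 ± 5 mm²/mg, LDMC 316 ± 80 mg/g, …); per-trait
  missing-value fractions (up to 12 % for the root-density traits)
  exercise the coverage rule at realistic rates.
* **Counts.** Zero-inflated Poisson, structural zeros with probability
  π = 0.35 on top of `Poisson(exp(β₀ + region + u_site + β·z(CWM)))`
  with β₀ = 0, region offsets (0, −0.1, 0.1), σ_site = 0.3 and
  β_SLA = 0.3. These give ~20 individuals per 30-core site and per-core
  counts in the observed 0–22 range. The Bernoulli mask is structural
  (not count-part-only) because the data it emulates are described only
  as severely zero-inflated, without a mechanism. Totals are split
  across eight families at fixed shares (Elateridae 43 %). Because the
  fitted model ignores the zero-inflation (absorbed into the intercept
  on the log-mean scale) and standardizes block means rather than the
  generator's plot-level CWM, the recovered slope on real pipeline runs
  is mildly attenuated relative to β; the estimation machinery itself
  is unbiased, which the block-level recovery harness (|bias| ≤ 0.05)
  checks directly.
* **Soil.** Lognormal around site means (water content 32.7 ± 18.8 %
  between sites with ~4 % within-site variation; root mass 0.6 ± 0.5 g;
  WHC 63 ± 26 %). Management draws F ∈ [0, 94] kg N/ha,
  M ∈ {0..3} cuts/yr, G ∈ [9, 1060] LU·d/ha, uniformly.
* Counts couple to the plant community only through the CWM of the
  focal trait; there is no independent spatial patch process for the
  larvae themselves, and no larval movement, oviposition behavior or
  multi-year dynamics. Passing tests therefore show the chain recovers
  structure *of the assumed form*; they cannot validate those
  behavioral mechanisms on real data.

## Determinism and problem sizes

All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning (simulation, permutations,
bootstraps each get independent streams), so a run is byte-reproducible
from its manifest. The test suite runs its calibration harnesses at
desk scale chosen for tight-but-cheap Monte-Carlo error: 500 null
transects at 199 permutations for the correlogram type-I check, 200
replicates of 28 × 10 fits for slope recovery, 200 outer replicates of
an 8-site design at 199 bootstrap draws for the bootstrap type-I check,
1000 transects for the Moran null. The acceptance script runs the full
28-site study at 199 permutations and 99 bootstrap draws.

## Known limitations

* The Laplace approximation can be biased for binary-like or very
  sparse counts; blocks of summed counts keep means high enough that it
  tracks the 10-node adaptive quadrature closely.
* The asymptotic LRT option for the Mantel-coefficient LMM is
  anti-conservative with few sites; use the bootstrap for inference.
* Backward stepwise selection inherits the usual caveats (selection
  uncertainty is not propagated into the retained model's standard
  errors).
* The correlogram excludes pairs beyond the last Sturges class; with
  other spacings than the 0.3 m design the number of excluded pairs
  changes with the bin geometry.
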