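# Methods

## The housing-quality outcome

A household's house type is classified from raw survey codes by four
deterministic rules: water source and sanitation facility are mapped to
improved/unimproved via WHO/UNICEF Joint Monitoring Programme category
tables; crowding is members per bedroom, with "more than three" flagged
(three persons per bedroom is acceptable); and construction materials are
classed natural/rudimentary/finished per component, with a house counted as
built of finished materials when at least two of roof, walls and floor are
finished ("rudimentary" counts as not finished). A house is *improved* iff
none of the four deprivations holds. Security of tenure, the fifth slum
criterion, is out of scope for lack of comparable data.

Lookup tables ship as editable CSVs because survey code dialects differ
between rounds. Classification is fail-closed: a household with any
unmapped or missing code is excluded from the aggregated counts and
tallied, never silently classed. Zero-bedroom households are treated as
one-bedroom (the common handling of single-room dwellings); an "exclude"
mode is available.

## The geostatistical model

Cluster-level counts are modelled as

    y⁺_c ~ BetaBinomial(n_c, μ_c, φ),
    μ_c = logistic(b₀ + √(σ²/M) βᵀ z(x_c|ω)),
    z(x|ω) = [cos(xᵀ ω̃_r), sin(xᵀ ω̃_r)]_{r=1..M},   ω̃_r = ω_r ⊙ relu(θ)

with inputs x = (covariates, planar x, planar y, year), standardized by
training means/sds that are stored with the fit. The trigonometric feature
map is the random-Fourier-feature approximation of a shift-invariant
Gaussian-process kernel k(x,x') ≈ (σ²/M)·z(x)ᵀz(x'); with standard-normal
frequencies it converges to the Gaussian kernel at the Monte-Carlo rate
O(M^{-1/2}).

**Parameterization of the beta-binomial.** α = μ(1−φ)/φ and
β = (1−μ)(1−φ)/φ, so μ is the regression mean and φ ∈ (0,1) acts as an
intra-cluster correlation: Var(y⁺) = nμ(1−μ)(1+(n−1)φ), with the binomial
recovered as φ→0. φ is fitted on the logit scale, σ² on the log scale.

**ARD scales.** Per-dimension unconstrained scales θ pass through a
rectified-linear transform; the effective frequency matrix is ω·relu(θ).
A scale reaching exactly zero removes that input from the kernel — sparse
covariate selection. No epsilon floor is applied: the exact zeros are the
point, and the relu dead zone makes zero absorbing during optimisation.

**Spectral measure.** Frequencies are initialised standard normal. By
default they are *not* individually adapted during fitting
(`learn_frequencies=False`): at desk scale (a few hundred clusters),
adapting the M×d frequency matrix adds ~10³ parameters, and in recovery
experiments it consistently overfit — the fitted surface chased the
cluster-level beta noise and the overdispersion estimate collapsed towards
zero. The data still shape the kernel through the ARD scales ("shrinking or
expanding" the base measure per dimension) and the amplitude. The
learned-frequency mode is retained as an option for larger datasets.

**Fitting.** Full-batch ADAM (step 0.01, default 6000 iterations) maximises
the dropout-regularized log-likelihood; dropout zeroes each of the 2M
feature activations independently with probability p (default 0.35) each
step, rescaling survivors by 1/(1−p). With dropout off, fits are
deterministic given the seed and stop early when the objective moves less
than 1e-7 over 100 steps. With dropout on, the gradient is stochastic; the
returned predictor averages μ over parameter snapshots from the second half
of the trajectory (a Monte-Carlo-dropout posterior mean), which is less
noisy than any single iterate. The default dropout rate 0.35 was chosen by
held-out beta-binomial likelihood on synthetic surveys; `select_dropout`
re-runs that random search (grid {0, 0.1, 0.2, 0.5}) on any dataset.
Heavy dropout (≈0.8) combined with a longer run is the recommended setting
when the goal is covariate *selection* (driving irrelevant ARD scales to
exact zero) rather than prediction. Selection reliability is
sample-size-dependent: a pure-noise covariate retains spurious in-sample
utility of order 1/√n, so at a few hundred clusters roughly half of noise
scales settle at small positive values, while at over a thousand clusters
every noise scale reaches exact zero in our studies with all genuine
covariates retained.

**Cluster-level estimates.** The surface μ(x) is the smooth component; a
cluster's own prevalence p_c is a beta draw around it. The fitted
cluster-level prevalence is therefore the empirical-Bayes posterior mean
E[p_c|y_c] = (y_c+α_c)/(n_c+α_c+β_c), which pools the surface prediction
with the cluster's observed rate under the fitted φ.

**Uncertainty.** The weighted likelihood bootstrap refits the model B times
(default 100) with per-observation likelihood weights n·w, w ~
Dirichlet(1,…,1), warm-starting at the point fit; member quantiles (2.5%,
97.5%) give 95% intervals. Surface intervals use member μ quantiles.
Cluster-prevalence intervals additionally mix the beta overdispersion layer
(draws from Beta(α_c, β_c) per member), since that layer is part of the
cluster's own prevalence; these predictive intervals are the ones whose
coverage is checked against the generator's known cluster prevalences.

## Validation

Random-split validation repeats a 75/25 partition ten times and averages
MSE and Pearson correlation at the cluster level and at the aggregate
survey level (unweighted means of cluster observations and predictions per
survey; the weighting of survey-level scores is a free choice and
population weighting is not applied there). Admin-unit holdout refits with
entire spatial blocks left out, which is the harder and more honest test
under spatial autocorrelation. All training statistics (standardization,
hyperparameters) are computed inside the training fold. The CRPS for an
ensemble X against observation y is estimated as mean|X−y| − ½·mean|X−X'|
with the double mean over all ordered member pairs, which degenerates to
the absolute error for a single member.

## Population-weighted aggregation

Stratum prevalence is Σ pop·μ / Σ pop over cells with non-missing surface,
per country × (urban / rural / all) with a static urban mask; cells with
population but missing surface are excluded from both sums and their
population is reported. Head counts are expected counts pop·μ and
pop·(1−μ); change between years is the difference of expected counts using
each year's own population raster (no cell-level flow decomposition is
attempted). A stratum with zero resolvable population is flagged undefined
rather than propagating NaNs.

## Household-level associations

Per survey, the wealth index is the first principal component of the
centred asset matrix after two inclusion filters (fewer than 10% missing;
ownership frequency strictly between 5% and 95%); the component is oriented
so electrification loads positively, and the wealth binary marks scores
strictly above the 75th percentile. PCA is on the covariance of the raw
binaries by default, with a `standardize` switch. Education is binarized as
more-than-primary; household-head age as over 55. Conditional logistic
regression (statsmodels, Newton iterations to tolerance 1e-10) estimates
the three log-odds-ratios within geographical cluster, dropping and
counting non-informative clusters; |log OR| > 15 flags separation and
excludes the survey from pooling. DerSimonian–Laird random-effects pooling
computes τ² from the Q statistic (floored at zero) and inverse-variance
weights 1/(SE²+τ²); with τ²=0 it reduces to fixed-effect pooling. Wald 95%
intervals on the log scale throughout.

## The synthetic-data generator

The generator emulates the structure of the real inputs at desk scale, on
an abstract unit-square grid (no projections): six covariate rasters built
from a fixed low-order trigonometric basis with random coefficients
(smooth, standardized per layer), a positive population raster, a static
urban mask (densest quintile) and country strips. The true prevalence
surface is drawn from the same RFF model family the estimator fits
(default 20 frequencies, amplitude 1, unit ARD scales, weight sd 1.2 around
a base prevalence of 0.25), so recovery is well-defined. Clusters are
sampled with probability proportional to population (two-stage PPS-style
selection), assigned survey years, and given beta-binomial counts with
φ_true = 0.1 — an intra-cluster correlation typical of household
infrastructure outcomes. Household attribute codes are drawn consistently
with each household's improved flag (an unimproved household violates each
criterion with configurable propensities, at least one always), so the
classifier round-trips the labels exactly.

Socioeconomic covariates are drawn iid at their marginal prevalences, and
the improved labels are then *reassigned within each cluster* (totals
unchanged) by exact conditional-Bernoulli sampling with weights
exp(Σ true-log-OR·x): conditional on cluster totals, this is precisely the
conditional-logistic model, so the generator's odds ratios (defaults 1.80
education, 2.53 wealth, 1.31 age) are exactly recoverable. A naive
per-covariate Bayes inversion would instead target marginal odds ratios and
bias the conditional estimates through non-collapsibility. Asset indicators
are generated from a latent wealth score with electrification loading
strongest, so the asset PCA aligns with the wealth binary.

All randomness flows from one root seed via `SeedSequence.spawn`: stream 0
covariate grid, 1 true surface, 2 cluster survey, 3 household attributes.

What the generator does **not** emulate: DHS recode file formats, sampling
weights, de-jure/de-facto membership distinctions, survey-year/time-trend
interactions (years are a free parameter), measurement error in cluster
coordinates, and real covariate collinearity. Passing recovery tests shows
the estimators are consistent under the stated model, not that real-world
biases (displacement, non-response) are handled.

## Numerical choices and scale

Desk-scale defaults keep every study inside a laptop-minute budget: M=100
features, 6000 ADAM iterations (≈10 s at 300 clusters). The bootstrap
warm-starts members and runs a quarter of the point fit's iterations. The
verification studies use reduced designs (coverage: 100 clusters, B=50,
M=40; association recovery: 60 clusters of 25 households) chosen so that
each study completes in minutes while leaving the checked property intact.
μ is clipped to [1e-10, 1−1e-10] inside the likelihood; a non-finite
objective raises a divergence error rather than returning garbage.

Observed recovery performance on default synthetic worlds (300 clusters,
one year): cluster-prevalence correlation ≥ 0.95; surface correlation
typically 0.87–0.96 (an oracle knowing the true frequencies reaches ≈0.95,
so the surface gap is representation and regularization, not optimisation);
φ̂ within roughly ±40% of the generating value. WLB predictive intervals
for cluster prevalence cover ≈97% empirically at the reduced design.

## Known limitations

- The fitted surface is a regularized point estimate; its own smoothing
  bias is visible as surface correlations below the oracle ceiling and is
  not corrected.
- WLB intervals for the *surface* (excluding the beta layer) undercover at
  small n because ensemble members share the point fit's bias; the
  predictive cluster-prevalence intervals are calibrated, the surface bands
  are heuristic.
- Exact zeros in the ARD scales depend on optimisation noise crossing the
  relu boundary; with light dropout, irrelevant covariates shrink but may
  retain small positive scales.
- The CLI pipeline re-fits rather than deserializing the model between
  stages; model JSON serialization is provided for external reuse.
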