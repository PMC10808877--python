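# Methods

This note records the package's modelling choices, the knobs that
matter, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-
engineer from the code.

## Climate summaries and environmental axes

Each grid cell's monthly series (at least 10 years) is reduced to six
statistics. Temperature variability is the SD of monthly values;
precipitation variability is the coefficient of variation (scale-free,
since precipitation is bounded below by zero). Predictability is
Colwell's information-theoretic index computed from a 12-month ×
*n*-state contingency table with `n_states = 11` equal-width bins
spanning each cell's min–max range; precipitation is log1p-transformed
before binning so that wet-season outliers do not swallow the bin
resolution. The bin count is fixed across cells for comparability. A
constant series returns (P, C, M) = (1, 1, 0) by convention: a flat
series is perfectly predictable and all of it is constancy.

The environmental PCA is a correlation PCA (columns standardized) over
land cells, unrotated; rotation is reserved for the predictor-reduction
PCAs where simple structure, not a dominant gradient, is the goal.
Sign anchoring is deterministic: PC1 is flipped if `temp_mean` loads
positively (so cold = harsh = high TH), PC2 if `precip_mean` loads
positively (dry = arid = high AI). Zero-variance columns are dropped
with a warning rather than imputed.

## Raster graph and least-cost paths

Land cells form an 8-connected lattice (16-connectivity available by
flag); every edge carries the haversine distance between cell centers
(mean Earth radius 6371.0088 km), which is the geographic correction
for the poleward shrinking of longitude steps. Environmental paths use
a start-relative per-cell cost c(v) = |env(v) − env(start)|, edge
weight w(u,v) = step · (c(u)+c(v))/2 + ε·step with ε = 1e−9. The ε
term breaks ties on zero-cost surfaces toward minimum-length routes;
reported accumulated costs exclude it, so a constant surface reports
exactly zero cost. Topographic paths use step · (1 + |Δelev|/run),
i.e. a unit multiplier plus rise-over-run slope magnitude — isotropic,
with no direction-dependent hiking function. Paths are computed with
Dijkstra on a sparse matrix; one source solve serves all destinations,
and cost/length are accumulated along the predecessor tree. Pair
records run each environmental surface in both directions, average
cost and length, take the (symmetric) topographic path once, and
log1p-transform cost/length fields (log1p rather than log guards the
zero-cost and same-cell cases). Societies snap to the containing grid
cell; coordinates on masked cells snap to the nearest land cell within
2 cells, else error. Disconnected pairs are excluded with a logged
count.

## Pair covariates

Pairs are each society's k = 100 geodesic-nearest neighbours,
de-duplicated (ties broken by id order). Sharing is recoded-code
equality; `missing` and `absent` are distinct markers that both yield a
missing flag, but only `absent` encodes the trait-specific exclusion
(societies in which the trait does not occur are not compared). Traits
with ≤2 recoded categories are rejected outright. Relatedness is the
patristic (cophenetic) distance on the language tree; polytomies are
used as-is. The neighbourhood-transmission statistic excludes *both*
pair members from the neighbour set — it is meant to capture
transmission from third parties, and including the partner would leak
the outcome into the covariate. The main mode uses the 5 nearest
societies *with data*; the sensitivity mode uses the fixed 10 nearest
regardless of data and keeps a pair only if ≥3 of the 10 have data on
both sides.

## Sharing models

The five varimax components are computed per trait (the transmission
covariate is trait-specific). Scores are standardized PC scores rotated
by the varimax rotation matrix, so they remain exactly uncorrelated
with unit variance; each component is sign-anchored so its
largest-|loading| raw variable loads positively (high score = high
barrier) and labeled by its dominant loading block via an optimal
assignment, which keeps "temperature turnover" etc. stable across
traits.

The Bernoulli mixed model uses one random-intercept variance shared
across the two society columns: the A/B labelling of a pair is
arbitrary, so a society's intercept must not depend on it. Estimation
is a Laplace approximation: for a candidate σ², a penalized IRLS Newton
solve finds the joint (β, u) mode; the profile objective
ℓ(β̂, û) − (q/2)·log σ² − ½·log det(ZᵀŴZ + I/σ²) is maximized over
log σ² by bounded scalar search (σ² ∈ [1e−6, 25]). At σ² → 0 the two
log-determinant terms cancel and the fit reduces smoothly to plain
logistic regression (verified to 1e−2 against a GLM, and against
lme4's glmer on a frozen fixture to ~0.1, the residual gap reflecting
glmer's two separate variances). Wald SEs come from the β block of the
inverse joint Hessian at the optimum, conditional on σ̂² — the same
convention as standard mixed-model software. AUC is the rank statistic
on conditional fitted probabilities. Correlograms use pair midpoints,
10 equal-count bins up to the 90th distance percentile, binary
within-bin weights, and one-sided permutation p-values (199
permutations by default).

Model filters apply verbatim: <50 complete pairs, sharing fraction
outside (0.10, 0.90), or non-convergence exclude a trait's model. FDR
adjustment is Benjamini–Yekutieli (valid under arbitrary dependence),
applied across traits separately per component.

## Origin corridors

Focal societies are those with an area label; their neighbour pools
draw on all societies. All nine primitive barrier metrics are kept as
columns (rather than pre-aggregated into seven), letting the PCA group
them and reporting the loadings — on realistic synthetic worlds the
close-range rotation reproduces the expected semantics (one travel
component spanning topographic costs, path lengths and geodesic; one
aridity-turnover; one temperature-turnover component). Close range
retains 3 components, long range 4.

Area comparisons use a two-stage variance-weighted fit: OLS on area
indicators, per-area residual variances, WLS refit with weights 1/σ̂ₐ².
Areas with fewer than 2 societies are dropped (no variance estimate).
Spatial structure is handled semi-parametrically: eigenvectors of
M·W·M (W = symmetrized row-standardized 5-NN weights, M the residual
maker of the current design) with positive eigenvalues are candidates;
the greedy loop adds the candidate that most reduces |Moran's I| of
the residuals and stops when the permutation p-value exceeds 0.1 or no
candidate improves. Tukey contrasts use the studentized-range
distribution on Tukey–Kramer statistics with Welch–Satterthwaite
effective degrees of freedom, an adaptation needed because the
variance-weighted fit gives each area its own variance. Paleo reruns
recompute only the climate-derived columns per timepoint; topographic
and geodesic columns are climate-independent and identical across
timepoints by construction.

## The synthetic world

The generator emulates the statistical features the analysis leans on,
not any real climate or history: a latitudinal temperature gradient
(28 − 0.45·|lat| °C) with a seasonal sinusoid whose amplitude grows
with |lat| (opposite phase across hemispheres) plus white noise; a
smooth precipitation field with latitudinal and longitudinal structure
whose seasonal amplitude rides the same seasonality knob (so the
noise-free limit is genuinely constant); low-pass-filtered Gaussian
terrain scaled to a target SD; societies jittered inside random land
cells; an ultrametric Yule tree (pendant edges extended by the common
waiting time to the next event, preserving ultrametry and positive
branch lengths); and trait histories with two causal routes. Vertical:
codes switch along each edge with probability 1 − exp(−μ·branch
length). Horizontal: one pass over societies in random order; each
draws a candidate donor uniformly from its `donor_pool_size` (default
10) nearest societies — diffusion is local; a global donor pool makes
any pair-level environmental signal undetectable — and copies with
probability logistic(α + β_dist·z(distance) + β_env·z(|ΔTH|)). The
z-standardization uses the realized (society, pool-donor) candidate
pairs: standardizing over all n² pairs would place every local donor
~1.5 SD below the mean and saturate the logistic, erasing the injected
contrast.

Defaults are one world "condition": 100 years of monthly climate (the
Colwell estimator is stable from ~20), 10 °C seasonal amplitude, 1 °C
temperature noise, 150 societies, 6 trait categories, μ = 0.2,
α = −1.0 (≈27% baseline copy rate), and both bias slopes zero — the
null world. Tests that need an effect use an explicit strong-bias
condition (β_env = −3, β_dist = −0.5, μ = 0.4, α = 0.5, pool 15),
under which the fitted temperature-turnover coefficient is negative in
20/20 replicate worlds.

What passing tests do *not* show about real data: the generator has no
coastlines or islands (the land-mask hook defaults to all-land), no
demography or range shifts, no correlated transmission of trait
packages, no observation bias in which societies carry data, and its
trait dynamics are a single-pass caricature of diffusion. Calibration
results (type-I rates, Tukey false-positive rates) therefore speak to
the statistical machinery under the stated generative assumptions, not
to the ethnographic record.

## Problem sizes and runtime choices

Worlds in the test-suite and acceptance script use 12×16 to 30×40
grids, 100–150 societies, and k = 25–100 neighbour designs (~1500–9000
pairs) — sizes at which every stage, including 100 per-trait mixed
fits, runs in seconds to a couple of minutes on one CPU while leaving
all qualitative behaviour (component structure, recovery, calibration)
intact. The bundled `configs/smoke.yaml` runs the full design
(30×40 grid, 150 societies, 10 traits, k = 100, 2500 km long range)
end to end in well under a minute.

## Known limitations

* The shared-variance crossed-intercept model understates dyadic
  dependence (sharing flags of pairs with a common member are more
  correlated than random intercepts imply); on heavy-copying worlds
  the env component's type-I rate rises to ~9% at α = 5%.
* Laplace estimates of σ² shrink toward zero on binary dyadic data
  (observed ~0.5 when the truth is 0.7); fixed effects are unbiased in
  our recovery experiments.
* Start-relative cost surfaces make accumulated cost scale linearly
  with the environmental gradient but ignore anisotropy (wind,
  currents, slope direction).
* The spatial-filter stopping rule (permutation p > 0.1) and the 5-NN
  weight design are conventions; different choices shift how many
  eigenvectors are absorbed.
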