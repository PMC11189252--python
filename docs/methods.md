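# Methods

This note documents the models and numerical choices behind `msngrad`: what
each stage assumes, which parameters matter, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely
open. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## MSN construction

Each subject's region × feature table (R regions, F ≥ 2 features; F = 5 by
default, 7 with diffusion-derived features) is column-z-scored across
regions with the sample standard deviation (n − 1), then the MSN entry
(i, j) is the Pearson correlation of the two regions' F-length normalized
feature vectors. Because z-scoring absorbs affine feature rescalings, the
MSN is invariant to units. With only F observations per correlation an
individual MSN is intrinsically noisy; group averages are far more stable,
which is why the template is built from the mean matrix. Degenerate inputs
(zero-variance feature, constant region profile) raise immediately rather
than propagating NaNs.

## Gradient manifold

Sparsification keeps, per row, the `floor(0.10 · R)` largest *signed*
correlations (the convention of gradient pipelines; negative ties at the
cutoff resolve to the lower column index for determinism). Cosine
similarity between the sparsified rows — computed on the asymmetric
thresholded matrix, symmetrized by construction of the cosine — gives the
affinity; the few negative cosines left after positive-dominant
thresholding are clipped to zero so the diffusion operator is well defined.

Diffusion map embedding uses density normalization α = 0.5 (approximating
Fokker–Planck diffusion, preserving global relations) and the automatic
diffusion-time convention for t = 0: component m is scaled by
λₘ/(1 − λₘ). Eigenvectors come from the symmetric conjugate of the Markov
operator (a dense symmetric eigenproblem — R is at most a few thousand);
the trivial λ = 1 eigenvector is removed by normalizing it to the constant
vector. Non-positive eigenvalues occur only for degenerate graphs (e.g. a
uniform complete graph) and carry no diffusion structure; their components
are collapsed to the origin. Sign indeterminacy is fixed by making each
column's largest-magnitude element positive. A disconnected affinity graph
is an error that reports component sizes: an embedding of a disconnected
graph would be meaningless, and with real group-average similarity
matrices it does not occur.

Individual embeddings are aligned to the group template with an orthogonal
Procrustes transform — rotation and reflection only. No scaling is allowed
because dispersion magnitudes must remain comparable across subjects; the
alignment is an isometry, so every dispersion statistic is invariant to it
(tested to 1e-10).

## Dispersion statistics

Centroids are unweighted means of region coordinates. Subject-level
dispersion statistics are *sums* (not means) of squared distances; regional
analyses use the unsquared eccentricity. Between-network dispersion is the
raw centroid distance (not its square). Useful identities used as test
oracles: global dispersion equals Σ eccentricity² and equals
(1/R)·Σ_{i<j} ‖xᵢ − xⱼ‖²; the within-network sum never exceeds the global
dispersion, with equality iff all network centroids coincide with the
global centroid.

## Harmonization (ComBat)

Parametric empirical-Bayes ComBat: per measure, a location model with site
intercepts and protected covariates (age, sex, eTIV in the pipeline) is
fitted; data are standardized by the pooled residual SD; per-site additive
(γ) and multiplicative (δ²) effects are shrunk across measures with a
normal prior on γ and an inverse-gamma prior on δ², hyperparameters
moment-matched, conditional estimates iterated to 1e-6. With a single site
the transform is the identity; with a single measure there is nothing to
pool and the direct estimates are used. Two properties worth knowing:
EB shrinkage removes the *systematic* (cross-measure) site effect exactly
but deliberately leaves part of each measure's in-sample sampling noise;
and harmonization is idempotent to within EB re-shrinkage of
already-centered effects. Harmonization is applied twice in the pipeline —
on vectorized MSN upper-triangle edges before template averaging and on
dispersion measures before trajectory fitting — both through the same
operation.

## Age trajectories

Gaussian location model y = f(age) + Xβ + ε with f a cubic B-spline
(10 basis functions, equally spaced interior knots; the intercept is
implicit in the spline and covariates are centered) and a second-order
difference penalty. The penalty weight is chosen by minimizing
GAIC = −2ℓ + k·EDF over a 25-point log-spaced grid (λ from 1e−2 to 1e8),
with penalty constant k = 3: k = 2 (AIC) admits visibly wiggly fits on
flat data whose locally steep derivatives create spurious "windows of
change", while k = 3 keeps curve RMSE and effect-size recovery unchanged
and reduces the false-window rate on flat trajectories to roughly half the
nominal level. Coefficient uncertainty uses the Bayesian posterior
covariance σ̂²(ZᵀZ + λP)⁻¹ of the penalized fit rather than the frequentist
sandwich: the posterior form is wider in penalized directions, accounts for
smoothing bias, and is what gives pointwise intervals near-nominal coverage
in GAM practice.

Effect sizes are Cox–Snell generalized pseudo-R² values,
1 − (L_reduced/L_full)^(2/n), against a reduced model with the age term
removed (intercept + covariates), signed by the slope of the fitted age
curve projected onto linear age. Developmental windows are contiguous runs
of a 100-point age grid where the pointwise 95% CI of the derivative —
obtained from 1,000 parametric draws of the spline coefficients — excludes
zero. Centile curves (25%/75%) come from the fitted location and either a
constant residual SD (default) or an optional log-linear SD in age. The
four age strata (8–19, 20–39, 40–59, 60–89 years) are available as
`AGE_WINDOWS` for stratified fits. FDR correction is Benjamini–Hochberg
via statsmodels.

## Mediation

Parallel OLS path models on z-scored variables (coefficients are
standardized βs): aⱼ from mⱼ ~ x + covariates, all bⱼ and the direct c′
jointly from y ~ x + m₁…m_J + covariates, and the total c from
y ~ x + covariates. Indirect effects aⱼbⱼ, joint Σaⱼbⱼ, proportion
mediated Σaⱼbⱼ/(Σaⱼbⱼ + c′). For identical covariate sets the in-sample
decomposition c = c′ + Σaⱼbⱼ is exact. Inference is a percentile bootstrap
over subjects (5,000 resamples by default; significance = 95% CI excluding
zero); reported p-values are bootstrap sign proportions
2·min(P(θ* ≤ 0), P(θ* ≥ 0)). Exactly collinear mediators raise an error
naming the pair — a chain where the mediator *equals* the exposure is
unidentifiable in this model class.

## Molecular association

Spin-test nulls rotate the unit-sphere parcel coordinates by a uniform
random rotation and map rotated to original parcels greedily
(globally-closest pair first), producing exact permutations that preserve
spatial autocorrelation. Permutation p-values use the finite-sample form
(1 + #extreme)/(1 + n_perm).

PLS1 is computed directly: weights w ∝ Xᵀy on z-scored inputs, scores Xw,
explained variance = squared correlation of scores with the response
(response-variance convention), sign fixed so the score–response
correlation is non-negative. Gene ranking follows the bootstrap-z recipe:
regions resampled with replacement, each bootstrap weight vector
sign-aligned to the original before the SE is taken, z = weight/SE, normal
two-sided p with an FDR mask, genes ranked by z, top-k list (k = 1,000 by
default). Bootstrap-z calibration degrades below ~100 regions (weight
normalization couples the genes), which is why the calibration tests use
R ≥ 100.

The receptor model is OLS on z-scored inputs with adjusted R² and the LMG
relative-importance decomposition computed *exactly* from the 2^P
subset-R² table (each predictor's incremental R² averaged over all P!
orderings); shares are non-negative for the model class used and sum to
the model R². Share CIs are percentile bootstrap; per-receptor spin
p-values refit the model on spin-permuted responses and compare
coefficients two-sidedly, FDR-corrected.

## Synthetic cohort generator

Each subject's region × feature table follows a latent-factor model

    X[r, f] = w_in(age)·U[k(r), f] + w_bt(age)·V[f]
              + w_sp(age)·(Φ W_s)[r, f] + site/sex shifts + σ·L_noise ε

with one standard-normal factor per network (U), one global factor (V), a
smooth spatial field (Φ: the top-12 eigenbasis of an RBF kernel on the
parcel sphere, width 0.8 chordal, rows scaled to unit average power), and
noise that is an equal mix of a spatially smooth component (RBF width 0.3)
and independent noise. Parcels sit on a Fibonacci lattice ordered by
latitude, so the contiguous network blocks are adjacent latitude bands.

Why the two smooth components exist: a pure block latent-factor model
yields a population-mean MSN whose top-10% thresholded graph disconnects
exactly into the networks — group-average similarity matrices from real
cortex never do this, because similarity declines smoothly across network
borders. The low-rank field supplies that smoothness at the population
level (connecting the template graph) and the smooth noise supplies it at
the individual level. Amplitudes are the smallest round values at which
embedding is well-posed for every subject.

Default couplings encode the study conditions: w_in(age) = 0.5 + 0.008·age
and w_sp(age) = 0.8 + 0.008·age, so both global and within-network
dispersion increase across the 8–89-year default age range; w_bt = 0.5 is
constant. Two empirical facts about this model worth recording: stronger
network coupling inflates the overall embedding scale while tightening
networks relatively, so w_in moves *global* dispersion strongly but
within-network dispersion barely; the spatial-field amplitude is what
directly disperses regions around their network centroid (the generative
analogue of within-community profiles becoming more heterogeneous with
age). And the global-factor coupling w_bt has no effect on the embedding
at all, because rank-based row thresholding removes uniform correlation
shifts; it is kept for completeness of the correlation structure.

Site effects are additive per-feature shifts plus multiplicative noise
scales (sites A/B/C at +0.0/+0.3/−0.2 and ×1.0/×1.1/×0.9) — exactly the
location/scale family ComBat models. Note that purely additive shifts
cancel in the MSN (z-scoring removes them); the noise-scale effects are
what propagate to dispersions and make harmonization consequential. Ages
are uniform over the range by default, with optional stratified sampling
over the four age windows; eTIV is Gaussian (1.5 ± 0.15 M mm³, +0.1 M for
males); behavior is generated from the stated mediation model with known
(a, b, c′); annotation maps are kernel-smoothed Gaussian fields with a
designated subset constructed to have an exact sample correlation ρ with a
target map.

What the generator does **not** emulate: realistic cortical geometry or
FreeSurfer feature scales, non-Gaussian feature distributions,
heteroscedastic aging noise, longitudinal structure, family structure, or
missing data. Passing tests therefore demonstrate that the implementation
recovers structure *of this generative class* at the stated sizes (60
subjects × 150 regions in the end-to-end checks, scaled so the whole suite
runs in minutes); they do not certify effect sizes on real cohorts.

## Determinism and degenerate inputs

Every stochastic stage takes an explicit seed (the pipeline derives all
stage seeds from one config seed); identical configs reproduce outputs bit
for bit. Degenerate inputs — constant measures, single-subject sites,
collinear designs, disconnected graphs, non-finite couplings — raise
errors naming the offending entity rather than returning silently wrong
numbers.
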