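# Methods

`disparikit` analyses the tempo and mode of morphological evolution in a
radiation of species on a time-calibrated phylogeny. This note documents the
models, the numerical choices, and what the synthetic data generator does and
does not emulate.

## Tree model and conventions

Trees are rooted, ultrametric (checked to a relative tolerance of 1e-8; a
failing input warns rather than errors, since consensus trees from Bayesian
dating often carry rounding), with branch lengths in time units (Mya by
convention; no unit conversion is performed). Polytomies are resolved
deterministically — children ordered by their smallest descendant label, then
laddered into zero-length internal branches — because all downstream GLS
algebra assumes bifurcation and zero-length branches leave the phylogenetic
covariance unchanged. Node heights are measured as time elapsed from the root
(root = 0, tips = tree height), so in the node-height test a *positive* slope
of |contrast| on height means rates accelerating toward the present. This
convention is recorded in the run manifest.

The Brownian covariance `C[i,j]` is the shared root-to-MRCA path length;
`C[i,i]` is the tip depth. Pagel's lambda multiplies the off-diagonal
entries; the early-burst transform integrates the decaying rate
`sigma2*exp(a*t)` (a <= 0) along shared paths, computed with `expm1` so the
BM limit a -> 0 is exact.

## Gaussian likelihood core

Every trait-evolution model is an exact dense Gaussian
`x ~ N(W beta, s V0)` with the structure matrix `V0` determined by the tree
and the model's nonlinear parameters. `beta` (optima / root state) and the
scale `s` are profiled analytically via a Cholesky factorization; `beta` is
computed by least squares on the whitened design so the profile remains
defined when a design column degenerates (a regime's selection exposure
vanishing as alpha -> 0). This leaves at most a two-dimensional numerical
optimization for any model.

Parameterizations and parameter counts (AICc uses
`-2 logL + 2k + 2k(k+1)/(n-k-1)`):

| model | free parameters | k |
|-------|-----------------|---|
| BM    | z0, sigma2 | 2 |
| EB    | z0, sigma2, a | 3 |
| OU1   | z0, sigma2, alpha, theta (z0 tied to theta) | 4 |
| OUMV  | z0, alpha, sigma2 x2, theta x2 (z0 tied to the root regime's theta) | 6 |

The OU root is fixed (non-stationary) at the optimum of the root regime. On
an ultrametric tree this makes the OU1 mean vector constant at theta, so z0
and theta are jointly represented by one value but counted per the
parameterization above. The OU covariance is
`V_ij = sigma2 exp(-alpha d_ij)(1 - exp(-2 alpha s_ij))/(2 alpha)` with `s`
the shared time and `d` the patristic separation.

For the multi-regime model the covariance decomposes by regime,
`V = sum_s sigma2_s A_s(alpha)` with
`A_s[i,j] = int exp(-2 alpha (T-u)) du` over the root->MRCA path segments in
regime `s`, and the mean design `W[i,s]` is the selection exposure of regime
`s` along the root->tip path plus `exp(-alpha T)` on the root regime's
column (rows sum to 1). Regime switches inside a branch split the transition
at the switch point. Optimization is over `(log alpha, log sigma2-ratio)`
with Nelder-Mead from three starts, one of them the single-optimum OU
solution, which guarantees the likelihood nests OU1 (and OU1's search in
turn evaluates the BM limit). Bounds: alpha in `[1e-8/T, 100/T]`, variance
ratio in `[1e-4, 1e4]`; hitting a bound sets a flag on the fit. Ties in the
lambda profile search are broken toward smaller lambda.

## Stochastic character mapping

The substrate-guild rate matrix is fitted by ML under the equal-rates Mk
model (all-rates-different available for two states) with a uniform root
prior. Histories are sampled by drawing node states from their conditional
distributions (pruning pass, then a root-to-tip pass) followed by
endpoint-conditioned path sampling on each branch: rejection sampling with
first-jump conditioning when the endpoints differ, falling back to
uniformization after 100 failed attempts. Every sampled history reproduces
the observed tip states exactly and tiles every edge (validated to 1e-12).
Model comparison fits OUMV on each of the `n_maps` histories (default 500)
and averages the per-map AICc arithmetically; each map's optimization is
additionally warm-started from the previous map's optimum. Maps whose fit
fails are dropped; more than 10% failures aborts.

## Phylogenetic signal, regression, ANOVA

Pagel's lambda is estimated by ML over `[0, lambda_max]` where `lambda_max`
is the largest value keeping the transformed covariance positive definite
(bisection, capped at 2), using a 21-point grid plus bounded refinement; the
p-value is a one-degree-of-freedom likelihood-ratio test against lambda = 0.
PGLS estimates the residual lambda by ML by default (recorded in the
result), with `sigma2 = RSS_gls/(n-p)` and t tests on `n-p` degrees of
freedom. The phylogenetic ANOVA compares the observed one-way F with F
statistics from BM simulations on the tree at the ML rate, with the add-one
rule `phylo-p = (#{F_sim >= F_obs}+1)/(n_sim+1)`; on a star phylogeny this
converges to the classical ANOVA p-value. All permutation/simulation
p-values use the add-one convention and are therefore never zero.

The phylogenetic PCA eigendecomposes the GLS-centered evolutionary rate
matrix `R = (X - mu)' C^-1 (X - mu)/(n-1)`; axis signs are fixed
deterministically (largest-magnitude loading positive) so outputs are
stable across runs.

## Ecological specialization (PDI)

The Paired Difference Index sorts a species' habitat scores descending,
normalizes by the row maximum, and averages the drops from the top score:
`PDI = sum_{i>=2}(P1 - Pi)/(H-1)`. This variant gives exactly 1 for a
single-habitat specialist and 0 for a uniform generalist and is invariant
to positive rescaling of a row; scores are validated as integers 0-3 over
9 habitats on input.

## Disparity through time

Disparity is the average pairwise squared Euclidean distance (the standard
metric of the DTT literature). At each internal-node time the curve averages
the relative disparity of the subclades whose stem lineage crosses that
time; the curve starts at exactly 1 and is closed with a 0 at relative time
1. The null envelope is `n_sim` BM simulations (default 1000, configurable;
the analysis is also run at 10,000 in some published settings) at the ML
rate (matrix) of the data. The MDI is the trapezoid-rule signed area between
the observed and null-mean curves over the full relative-time axis [0, 1]
(an optional cutoff restricts the range); its p-value is one-sided
(observed >= null), matching the reading that a positive MDI means disparity
concentrated within subclades. The node-height test regresses |standardized
contrast| on node height by OLS.

## Geometric morphometrics

GPA translates configurations to the origin, scales to unit centroid size
(full Procrustes), and iteratively rotates to the consensus with proper
rotations only (no reflections) until the consensus moves by less than
1e-10 (error after 1000 iterations). Tangent-space coordinates are the
aligned coordinates themselves: at the small shape variation simulated and
analysed here the orthogonal projection at the consensus differs negligibly,
which we verified numerically. Species mean shapes are coordinatewise
averages of aligned specimens; the shape PCA is a covariance PCA of the
flattened means with the same deterministic sign convention. The allometry
check regresses all shape coordinates on log centroid size and permutes the
size labels (statistic: model sum of squares; add-one p). Size correction of
linear traits uses log-log OLS residuals on structural body length — the
least-assumption reading of "size-corrected"; a ratio-based alternative can
be had by dividing traits by body length before the call.

## Synthetic data generator

The generator emulates the study conditions: a 70-species Yule tree
(rescaled to height 100, Mya-like), two substrate guilds evolving under a
symmetric Markov chain with ~2 expected transitions per root-to-tip path,
3-5 male specimens per species, 14 head landmarks, and a 9-habitat
association matrix with integer scores 0-3. Linear traits are log-normal
with isometric allometry on structural body length plus Brownian deviations;
the femur width/length ratio and relative tegmina length carry
guild-dependent OU optima (stouter femora and shorter wings on the ground
guild, alpha = 3 per tree height); relative antenna length increases with
ecological specialization with slope 0.3, the generator's ground-truth
regression effect. Specialization itself is a rescaled Brownian trait, so
PDI carries phylogenetic signal. Landmark configurations add species-level
Brownian shape deviations, specimen-level isotropic digitization noise
(sd 0.01 at unit centroid size), and a random similarity transform per
specimen (rotation Uniform(0, 2pi), log-scale Normal(0, 0.1)) so the
Procrustes step has real work to do.

Continuous traits use the exact OU Gaussian transition per branch segment
(no Euler discretization); discrete histories use exact Gillespie
simulation. All generators draw from named child streams of a single root
seed, so equal seeds give bitwise-equal outputs and changing the number of
draws in one stage does not perturb another.

What the generator does *not* emulate: measurement correlation between
specimens, digitization error that varies with landmark, missing data,
fossil tips, non-ultrametric trees, or selection regimes with more than two
states. Passing tests therefore demonstrate correctness of the estimators
under the stated generating processes, not robustness to those real-data
complications.

## Problem sizes used in the test suite

The acceptance checks run at the study scale of 70 species with 100
replicates for parameter recovery, 500 replicates (500 simulations each) for
ANOVA calibration, 100 datasets (200 null simulations each) for DTT
self-consistency, and 50 replicates with 50 stochastic maps for model
selection; the end-to-end run uses 500/200/50 for the ANOVA/DTT/map counts.
These sizes were chosen so the whole suite completes comfortably on one CPU
while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* OUMV fitting supports exactly two regimes (the study design); the
  likelihood machinery itself is written for k regimes.
* No regime-specific alpha (OUMVA), no multivariate-response OU, no
  measurement-error models, and no Bayesian fitting.
* Blomberg's K is not implemented (lambda is the signal statistic used).
* The lambda LR test uses the chi-square reference despite the boundary at
  lambda = 0, matching standard practice; boundary-corrected p-values would
  be roughly half as large.
* Thin-plate-spline deformation grids are limited to coordinate exports; no
  figure rendering anywhere in the package.
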