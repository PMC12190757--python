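# Methods

## Model and procedure

`reko` implements a fixed-design knockoff construction. The feature matrix
X (n samples × p features) is treated as fixed and known; every statement
about covariances is a statement about *sample* moments, computed on
centered columns with divisor n − 1 throughout the package. Columns are
standardized to mean 0 and sample variance 1 before anything else; constant
columns are rejected rather than silently dropped.

### Reflection

For each feature j, the Householder reflection over the hyperplane spanned
by the other features is Y_j = 2X̂_j − X_j, with X̂_j the least-squares fit
of X_j on X_{,−j}. Writing Z = (X − Y)/2 (the regression residual), four
exact identities hold on any full-rank standardized X:

- cov(Y_j, X_k) = cov(X_j, X_k) for j ≠ k — the reflection preserves all
  cross-covariances, which is precisely what a knockoff must do;
- cov(Y_j, X_j) < var(X_j) strictly — the reflection decorrelates each
  feature from its own copy;
- T = cov(X, Z) is diagonal with T_jj = var(Z_j) > 0;
- Y and Z lie in the column space of X.

The computation follows one QR factorization of X: removing column j of R
leaves an upper-Hessenberg matrix that at most p − j Givens rotations
re-triangularize, after which a back-substitution gives the per-column
regression. This is algebraically identical to p separate normal-equation
solves (the test suite checks entrywise agreement at 1e−8) at O(p³) total
cost instead of O(np³). Rotations are applied left-to-right on the columns
right of the removed one; the ordering cannot affect the least-squares
solution, which is unique on full-rank input.

### Scaling the decorrelation: S = α̂T

With C = cov(Z T^(−1/2)) = QΛQᵗ, the conditional covariance of the
knockoff given X is T^(1/2)Q(2αI − α²Λ)QᵗT^(1/2), PSD exactly when
α ≤ 2/Λ₁. The package uses α̂ = min(1, 2/Λ₁) — the cap at 1 keeps the
conditional mean X − α̂Z a contraction of the reflection; the unclipped
value is surfaced in diagnostics. C has unit diagonal (without
augmentation), and for a pair of standardized features at correlation r the
off-diagonal entry is −r, since cov(Z₁, Z₂) = r(r² − 1) and
var(Z_j) = 1 − r²; both nearly-duplicate and nearly-independent features
therefore produce small off-diagonals, and by the Gershgorin circle theorem
Λ₁ stays near 1, keeping α̂ bounded away from 0. Eigendecomposition runs on
the symmetrized (C + Cᵗ)/2. When C is numerically diagonal (max
off-diagonal ≤ 1e−12) its eigenbasis is degenerate and `eigh` would return
an arbitrary rotation; the package fixes Q = I in that case, which also
makes the uncorrelated special case X̃ = U hold exactly. Entries of
2α̂ − α̂²Λ_j that dip below zero by floating-point noise are clipped before
the square root.

### Noise modes

`gaussian` (default): each column of U is i.i.d. standard normal; the
knockoff second moments hold in expectation, with O(1/√n) sample
deviations. `nullspace`: U is an orthonormal basis of the complement of
span([X, 1]), scaled by √(n−1) so each column has unit sample variance.
Including the constant vector keeps U exactly centered, which is what makes
the sample covariance identities exact (the test bar is 1e−6); it costs one
extra dimension, so this mode needs n ≥ 2p + 1. The basis itself is
arbitrary (any orthonormal basis of that complement yields a valid
knockoff); the package takes the first p columns of a full orthogonal
decomposition.

### Shrinkage priors and ghost samples

Highly correlated features make var(Z_j) collapse toward 0, draining the
filter's power. A ridge prior β ~ N(0, τ⁻¹σ_j²I) on each column regression
is implemented by appending p ghost rows diag(1/σ_j) to X, which reproduces
the ridge normal equations exactly and keeps the augmented matrix full rank
for any shape — including p > n. After augmentation cov(X, Z) on the
original n rows is no longer exactly diagonal; T is *defined* as its
diagonal, and the largest ignored off-diagonal is reported as a diagnostic
(`max_offdiag`).

The prior variances σ_j² are estimated by empirical Bayes. Rotating the
marginal model by the eigenvectors of X_{,−j}X_{,−j}ᵗ = QDQᵗ and profiling
the precision τ analytically at its ML value gives, up to a constant,

    ℓ(σ²) = −(m/2)·log Σᵢ u_i²/(σ²d_i + 1) − ½·Σᵢ log(σ²d_i + 1),

with u = QᵗX_j. τ is profiled in closed form rather than jointly iterated —
the profile is exact, so nothing is lost. σ_j² is maximized by bisection on
dℓ/dσ² over [1e−6, 1] to tolerance 1e−6: the upper bound 1 is a practical
cap for standardized regressions; the lower bound and tolerance are this
package's declared choices. When the derivative has one sign on the whole
interval the better endpoint is returned and flagged `boundary`; when the
likelihood carries no information (all d = 0) the default σ_j² = 1/p is
filled in and flagged `flat`. 1/p is also the fixed-prior fallback
(`priors="fixed"`): it keeps the posterior proper as p grows.

A dense eigendecomposition per feature would cost O(np³) overall. Instead
the eigenvectors of XXᵗ are shared and only eigenvalues are downdated:
X_{,−j}X_{,−j}ᵗ = XXᵗ − x_jx_jᵗ, whose eigenvalues are roots of the
secular equation 1 − Σ z_i²/(d_i − μ) = 0 with z = Qᵗx_j. The secular
function is strictly decreasing between poles, so each root is bracketed by
the interlacing bounds d_{i+1} ≤ μ_i ≤ d_i (d_m − ‖z‖² for the smallest)
and found by bisection, vectorized over all roots; coordinates with
negligible z_i are deflated. Crucially, the rotated response is *also*
mapped into the downdated eigenbasis via the rank-one update formula
v_i ∝ (D − μ_i)⁻¹z. Skipping that step misattributes the regression
residual of x_j — which belongs to the new near-zero eigenvalue direction —
across the retained spectrum and drives σ̂_j² to the upper boundary; with
it, the rank-one-update mode agrees with per-feature dense
eigendecompositions to machine precision when all nonzero eigenpairs are
retained (for p ≤ n these come cheaply from the p × p Gram matrix). The
`rsvd` mode substitutes randomized top-k eigenpairs (Gaussian sketch,
10 oversamples, 2 power iterations; default k = min(200, n, p)); with
k below the rank of X the truncated tail degrades the per-feature
likelihoods, so k ≥ rank is recommended whenever affordable.

### Importance measures and the filter

The `beta` measure fits an L1-dominated elastic net (l1_ratio = 0.95) of
the centered phenotype on the 2p columns of [X, X̃] and reports absolute
coefficients. The small ridge component makes the optimum unique, so
duplicated or exchangeable columns split credit symmetrically instead of
one arbitrarily absorbing it — without it, the statistic of a feature whose
knockoff is nearly identical to it would be solver-order noise. Column
order is randomly permuted per seed before fitting so path order cannot
favor originals over knockoffs. The penalty is chosen by 5-fold
cross-validation over 50 candidates; a fixed-penalty mode exists for
reproducibility studies.

The `pip` measure is a spike-and-slab Gibbs sampler over [X, X̃]:
γ_j ~ Bernoulli(π₀), β_j | γ_j = 1 ~ N(0, v·σ²), σ² under a Jeffreys
prior; defaults π₀ = 1/p, v = 1, 2000 sweeps with 500 burn-in. Single-site
updates mix poorly across near-collinear features (the chain rarely swaps
which member of a correlated clique is "in"), so each sweep is followed by
Metropolized swap proposals exchanging an included column with an excluded
one, with both betas integrated out conditional on the rest. On small
instances where the posterior can be enumerated exactly (the conjugate
marginal likelihood is closed-form), the sampler's inclusion probabilities
match enumeration to within 0.03–0.08, including the model-averaging
regime where four indistinguishable proxies of one signal each receive
PIP ≈ 1/4 — the behavior that motivates intersecting the Beta and PIP
selections in the combined filter.

The knockoff statistic is W_j = importance_j − importance_{knockoff j}, and
the threshold is the smallest candidate t (over nonzero |W_j|; a grid-free
minimum over all t > 0 is attained at one of these) with
(#{W_j ≤ −t} + offset)/max(#{W_j ≥ t}, 1) ≤ q; offset 1 (`knockoff_plus`)
carries the exact finite-sample FDR guarantee, offset 0 is the default.
Aggregation computes the threshold from the concatenation of M statistic
vectors and selects W̄_j ≥ T_cat. Selection uses ≥ (the counts in the
threshold definition use ≥ t); with continuous statistics the boundary
convention is immaterial, and a 1e−12 relative guard absorbs the one-ulp
perturbation that averaging M identical copies can introduce. The
aggregation argument assumes non-null features have W_j^(m) > 0 in every
copy — for weak signals this can fail, in which case averaging dilutes them;
aggregation helps most when signals are moderately strong, as the power
comparisons in the test suite reflect.

## Synthetic data and what the tests do (and do not) show

The generator produces Gaussian features with independent, AR(1)(ρ) or
block-equicorrelated covariance, standardized; phenotypes are linear with a
uniformly drawn causal set, i.i.d. standard-normal effects, and noise
variance var(Xβ)(1 − pve)/pve so the realized proportion of variance
explained matches the target in expectation. Benchmark defaults — n = 800,
p = 150, AR(1) ρ = 0.5, 20 causal features at PVE = 0.5, M = 3 copies,
knockoff+ at q = 0.10, 100 replicates, pooled (not per-replicate-averaged)
power and FDR — are the package's reference study conditions. Greedy
trimming of feature pairs above a correlation threshold (dropping the
weaker marginal association, or a random member) is provided for real-data
preprocessing; pairs are visited in order of decreasing |correlation|,
which makes the pass deterministic.

Gaussian features with stationary correlation are a favorable regime: real
dosage matrices are discrete with blocky, non-stationary LD, and abundance
panels have heavy tails and shared technical noise. Passing tests here
demonstrate correctness of the algebra and calibration under the stated
designs, not FDR control under arbitrary covariance — the construction
matches second moments only, and no distribution-free guarantee is claimed.
Non-Gaussian margins can be emulated by passing a user matrix
(`structure="from_matrix"`).

## Numerical choices and degenerate inputs

- Sample covariance divisor n − 1 everywhere (null-space noise is rescaled
  accordingly).
- Rank deficiency without augmentation is detected from the R diagonal
  (relative tolerance 1e−10) and reported with guidance to enable
  augmentation; p = 1 inputs are rejected (reflection undefined).
- All-zero statistic vectors threshold to +∞ with a warning (nothing
  selectable).
- Equicorrelated second-order Model-X knockoffs (the baseline comparator)
  use S = min(1, 2λ_min)I on a Ledoit–Wolf-shrunk correlation estimate by
  default; the unshrunk estimator errors on singular covariance.
- One top-level seed fans out into named substreams (features, phenotype,
  knockoff noise per copy, CV folds, Gibbs, trimming), so any component is
  reproducible in isolation and runs are byte-identical given config + seed.

## Problem sizes

Default test-suite simulations run at n = 300–400, p = 60–80 with 15–40
replicates; the acceptance script runs the reference conditions above
(n = 800, p = 150, 100 replicates, roughly ten minutes on one core). These
sizes were chosen so the Monte-Carlo standard errors quoted in the tests
(binomial, pooled) are small relative to the bands being checked.

## Known limitations

- FDR control is empirical for the plain `knockoff` variant; only
  `knockoff_plus` carries the finite-sample guarantee, and no theoretical
  guarantee exists under arbitrary covariance structure.
- The rank-one-update prior path is exact only when all nonzero eigenpairs
  of XXᵗ are retained; truncated rSVD spectra bias σ̂_j² upward.
- The Gibbs sampler's swap moves help within-clique mixing but very large
  collinear cliques (tens of members) may still need longer chains.
- VCF/PLINK/BGEN parsing is out of scope: genotype users convert to
  delimited dosage matrices first. Mixed-model residualization (kinship
  adjustment) is expected to happen upstream.
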