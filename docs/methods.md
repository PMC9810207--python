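# Methods

## Model

A multi-environment trial records a phenotype `y_ijr` for genotype *i* in
environment *j*, replicate block *r*.  The AMMI (additive main effects
and multiplicative interaction) model in vector form is

    y = X1 β + Z g + Σ_{k=1..t} λ_k diag(Z α_k) X2 γ_k + ε,   ε ~ N(0, σ_e² I)

with `X1` the incidence of blocks nested within environments (`e·r'`
columns), `X2` the incidence of environments, `Z` the incidence of
genotypes.  The bilinear terms are the singular value decomposition of
the double-centered genotype-by-environment interaction (GEI) matrix:
`λ_1 ≥ … ≥ λ_t ≥ 0`, and the genotypic scores `α_k` (length *g*) and
environmental scores `γ_k` (length *e*) are unit-norm, mutually
orthogonal and centered (orthogonal to the ones vector).  Blocks are
always nested within environments; this keeps every parameter identified
without sum-to-zero side conditions.  Unbalanced data (empty
genotype-by-environment cells) are handled natively by the incidence
structure.

Priors: `β` flat (Gaussian with variance 1e8); `g ~ N(0, σ_g² I)` with
`p(σ_g²) ∝ 1/σ_g²`; `p(σ_e²) ∝ 1/σ_e²`; each `λ_k` positive truncated
normal `N⁺(0, σ_{λk}²)`; scores uniform on the sphere of the admissible
subspace; the dimension `t` truncated-Poisson(μ) on `{0, …, t_max}` with
`t_max = min(g, e) − 1`, and `μ ~ Gamma(τ, υ)` (defaults τ = υ = 1).

The three prior families differ only in the singular-value scale:

| family | prior on σ_λk² | conditional given λ_k | effect |
|---|---|---|---|
| BAMMI  | fixed 1e8 | none | effectively flat λ |
| BAMMIS | ∝ (σ²)^(Δ−1), 0<Δ<1/2 (default 1/4) | InvGamma(1/2−Δ, λ²/2) | mild shrinkage |
| BAMMIE | InvGamma(a=1, b=0) (maximum entropy) | InvGamma(3/2, λ²/2) | aggressive shrinkage |

The BAMMIE marginal prior on λ (scale integrated out) behaves like
λ^(−3): a sharp spike at zero.  In the chain this appears as a
near-absorbing collapsed regime — once a singular value wanders low, its
scale follows it down and pins it — which is precisely the mechanism
that prunes noise axes.

## Samplers

**Gibbs sweep (fixed t).**  All full conditionals are conjugate.  The
linear effects (β, g) are drawn *jointly* from their exact Gaussian
conditional: updating them one at a time random-walks the level that can
move freely between block and genotype effects (pinned only by the
genotype prior) and produced Raftery–Lewis dependence factors near 8; the
joint draw, a (n_cells+g)-dimensional Cholesky solve, brings every
monitored dependence factor close to 1 while leaving the stationary
distribution untouched.  The printed one-at-a-time conditionals remain in
the public API and are verified against closed forms in the tests.

Each axis k then updates in order: `λ_k` from a truncated normal with
precision `φ_k'φ_k + σ_e²/σ_{λk}²` (φ_k = diag(Zα_k)X2γ_k), truncated to
`(0, λ_{k−1})` with λ_0 = +∞ so ordering is maintained by construction;
`σ_{λk}²` per the family; `α_k` and `γ_k` from von Mises–Fisher
distributions restricted to the subspace orthogonal to the ones vector
and all other vectors of the same side.  The vMF natural parameter fuses
concentration and direction: `(λ_k/σ_e²)·Δ'(residual)`; for balanced
data the quadratic term `α'Δ'Δα` is constant on the sphere, making the
vMF form exact.  Subspace draws project the natural parameter onto the
orthogonal complement, sample there (Ulrich–Wood rejection), and map
back; a numerically zero projection falls back to a uniform draw.
Variances are scaled-inverse-χ²; μ gets the conjugate `Gamma(τ+t, υ+1)`
update (the truncated-Poisson normalizer is ignored — immaterial when
`t_max` is rarely binding).  The printed μ conditional ("Gamma(τ, μ)")
is not a valid distribution; the conjugate form is used.

Initialization: least-squares additive fit, axes seeded from the SVD of
the residual cell-mean interaction, variances from residual moments.

**Reversible jump.**  One dimension move per sweep, chosen with
probabilities (pa, pd, p0) = (1/3, 1/3, 1/3): a *birth* appends axis t+1
with scores drawn uniformly in the admissible subspace (their
conditional at λ = 0), λ from its data conditional under a flat scale
truncated to (0, λ_t), and the scale from the family conditional — so
the dimension-matching Jacobian is one; a *death* removes the last
(smallest) axis.  Log acceptance ratios:

    birth:  [ℓ(t+1) − ℓ(t)] + log μ − log(t+1) + log(pd/pa)
    death:  [ℓ(t−1) − ℓ(t)] + log t − log μ + log(pa/pd)

with ℓ the Gaussian log likelihood at the current/proposed parameters.
These are exact mirror images, so with the likelihood ratio forced to
one the stationary distribution of t is its prior — verified by a χ²
goodness-of-fit test against the closed-form marginal
`p(t) ∝ Γ(t+τ) / (t! (1+υ)^t)` (the Gamma hyperprior integrated over the
conjugate μ update).  A commonly printed variant of these ratios carries
extra `1/(t+1)` and `t` proposal factors; a transition-matrix computation
(numerical integration over μ) shows that variant concentrates nearly
all mass at t ∈ {0, 1} under a flat likelihood, i.e. it fails prior
recovery by orders of magnitude, so this package uses the
detailed-balance-consistent form above.  The selected model is the
dimension with the highest visit frequency (ties toward smaller t).

## Synthetic trials

`simulate_trial` reproduces a randomized-complete-block trial: defaults
g = 20, e = 9, r = 3 (540 plots); genotype effects N(0, 12); environment
effects N(0, 1); GEI from three subgroups — genotypes 1–5 take
half-normal |N(0, 16)| effects positive in environments 1–4 and negative
in 5–9, genotypes 6–10 the mirror image, genotypes 11–20 N(0, 1)
(stable); draws are independent per cell; the matrix is double-centered;
block effects are exactly zero (no distribution is specified for them);
plot error N(0, 2.5).  All normal distributions are parameterized as
mean/variance.  `svd_truth` reports the singular values of the planted
interaction; the sum-of-squares convention is cell-level, `SS = Σ λ_k²`
of the g×e matrix, with no replicate factor.

A property of these defaults worth stating plainly: per-cell half-normal
draws with variance 16 leave substantial *within-sign-block* variation,
so the planted interaction is effectively full rank — all eight singular
values are large relative to the cell-mean noise (sd ≈ 0.91), and its
total SS is ≈ 1100–1300.  Reference results in the literature for this
design correspond to a much weaker, effectively rank-3 interaction
(SS ≈ 260); no literal reading of the stated recipe reproduces that
scale.  Consequences on these defaults, observed in the tests: the
reversible-jump modal dimension is high for the flat prior (≈ 8) and
smallest for BAMMIE (≈ 4, still > 2), and the attainable predictive
correlation under 10% whole-cell loss is capped near 0.78 (main effects
carry 13/22.5 of the phenotypic variance here, versus ≈ 13/17 in the
weak-interaction regime where 0.81–0.89 is attainable).  The generator's
defaults are the stated study conditions and are not adjusted to move
these outcomes.

`planted_rank_trial` plants an exactly low-rank interaction from random
centered orthonormal score vectors (default λ = (13, 8), chosen at the
scale of the leading reference singular values) and is the basis of the
parameter- and rank-recovery checks.

## Summaries, selection, prediction, diagnostics

*Conditional* summaries use iterations with t = t*; *marginal* summaries
use t ≥ t*, truncated to the first t* axes.  Score draws are
sign-aligned (joint flip of (α_k, γ_k) against the first retained
iteration) before averaging; point-estimate score matrices U, V are then
QR-orthonormalized (positive diagonal).  Biplot credibility regions are
normal-approximation ellipses from the posterior moments of each
entity's first two score coordinates at the χ²₂ quantile; an entity is
*stable* when the origin's squared Mahalanobis distance is inside the
quantile.  Regions are computed from aligned raw draws; orthonormalization
applies only to the point estimates.  Scores are raw singular-vector
coordinates (no λ^½ scaling).

AIC/BIC plug posterior means into the deviance and count parameters with
Gollob's per-axis degrees of freedom (g + e − 1 − 2k); AICM is
−2·(mean − variance) of the posterior log-likelihood draws.

Cross-validation withholds whole genotype-within-environment cells (all
replicates at once), 10% of cells per fold over 10 folds, under the
constraint that every genotype and environment keeps at least one
training record; fold plans are rejection-resampled until the constraint
holds.  Withheld records are predicted by the posterior-mean response;
an unseen block cell falls back to the environment's mean block effect;
reversible-jump fits predict from the marginal response at the modal
dimension.  Metrics: Pearson correlation and PRESS (mean squared
prediction error).

Raftery–Lewis run-length control uses the canonical settings
(q, r, s) = (0.025, 0.005, 0.95); Heidelberger–Welch stationarity uses
the Cramér–von Mises statistic on the partial-sum bridge with an
AR-based spectral-density-at-zero estimate and 10% initial discards up
to 50%; verdicts compare against asymptotic critical values.  Monitored
traces: variances, μ, log likelihood, singular values shared by all
retained dimensions, and the first genotype effect.  The pilot option
runs 500 sweeps and takes burn-in/thinning from Raftery–Lewis.

## Numerical choices and limitations

- Truncated-normal draws via the inverse-CDF (scipy), stable far in the
  tails; a collapsed upper bound (λ_{k−1} ≤ 0) degrades to an interval of
  width 1e-10 rather than failing.
- Inverse-gamma scales are clamped to [1e-12, 1e12]; degenerate rates to
  1e-300.
- vMF dimension 1 (fully constrained complement) is sampled exactly as a
  two-point distribution.
- At t = 0 / t = t_max the death/birth move is skipped without
  re-normalizing move probabilities; prior recovery is validated with
  t_max = 8 where truncation is immaterial.
- The sampler assumes homoscedastic residuals and no covariates or
  spatial effects; the generator does not emulate heteroscedasticity
  across environments, block-effect structure, or missingness beyond the
  cross-validation loss pattern, so passing tests say nothing about
  those features of real trials.
- Chain lengths in the test suite and reproduction script are modest
  (600–12000 sweeps, chosen as the package's working sizes); every
  reported quantity is recomputed at run time at those sizes.
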