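# Methods

## Model

For n species on a rooted phylogeny with branch lengths, the response
Y = (y₁,…,yₙ) holds nonnegative counts and X is an n×(p+1) design matrix
with an intercept column.  Two conditional families are supported:

* Poisson, log link: μ = V = exp(η), η = Xβ.
* NB2 negative binomial with dispersion r > 0: variance V = μ + μ²/r
  (Poisson recovered as r → ∞).  Two links: log (μ = exp(η), the convention
  for empirical fitting) and canonical (θ = log(μ/(μ+r)), so
  μ = r·e^η/(1−e^η), defined only for η < 0; used for simulation parity).

Dependence between species enters through C, the matrix of shared
root-to-MRCA branch lengths: c_ij is the depth of the most recent common
ancestor of tips i and j and c_ii the root-to-tip depth.  Under Brownian
motion a continuous trait has covariance σ²C; here C plays the role of the
working covariance scaffold for counts.

Coefficients solve the generalized estimating equations

    U(β) = Dᵗ W⁻¹ (Y − μ) = 0,   D = diag(dμ/dη)·X,   W = S^{1/2} C S^{1/2},

with S = diag(V(μᵢ)).  Properties relied on throughout:

* C ∝ I (star tree) reduces U to the GLM score Xᵗ(Y − μ), so the GEE
  estimates equal the independent MLEs there;
* multiplying C by any positive constant (changing the tree's time units)
  rescales U without moving its root, so estimates are invariant to uniform
  tree rescaling.

The NB2 working matrix uses the full NB2 variance in S by default.  A
variant with S = diag(μ) is available (`working_variance="mean"`); it exists
because the two readings of the working matrix differ only in whether the
overdispersion term enters the weighting, and the default is the one that
makes the star-tree reduction exact for the NB2 score.

r is never estimated inside the GEE: it is either supplied by the user or
taken from the independent NB2 MLE.  The exponential-family scale a(φ) is
fixed at 1 for both families, so no extra dispersion factor enters U.

## Solver

Damped Fisher scoring on U(β): Newton direction (Dᵗ W⁻¹ D)⁻¹ U, step-halving
(up to 30 halvings) until the score norm decreases and, for the canonical NB2
link, the predictor stays in-domain; at most 100 iterations.  Starting values
come from the corresponding independent GLM (mapped through the means onto
the canonical-link scale where needed); for saturated problems (n ≤ p+1) a
least-squares fit on the link scale of the shifted counts.

Convergence is declared when max_j |U_j| / max(1, √J_jj) < 1e−8, with
J = Dᵗ W⁻¹ D.  The standardization makes the test invariant to the scale of
the counts: with means of order 10⁷ (which the simulation's log-linear model
produces routinely) the raw score's floating-point floor exceeds any fixed
absolute tolerance even at the exact root.  W is inverted by Cholesky, with
an SVD pseudo-inverse (relative cutoff 1e−10, configurable) when the
factorization fails; the condition number of W and whether the pseudo-inverse
path was taken are reported on every fit.  Non-convergence is flagged, never
silently dropped.

## Independent baselines and model comparison

The Poisson MLE is an IRLS GLM fit (statsmodels).  The NB2 MLE is a profile
fit: for fixed r, β comes from an IRLS fit with the NB2 variance function;
the exact NB2 log-likelihood is then maximized over log r on [1e−3, 1e6] by
bounded scalar optimization.  The profile approach is robust where joint
Newton updates diverge: for data with no overdispersion the profile optimum
sits at the upper bound, and r is capped there with a warning (the fit is
then effectively Poisson).  An all-zero response is rejected (the MLE
diverges).

Models are compared by AICc = AIC + 2k(k+1)/(n−k−1) (k counts the estimated
parameters: p+1 for Poisson, p+2 for NB2 with estimated r) and Akaike
weights, the softmax of −AICc/2 relative to the best model.

## Simulators

**Covariates.**  x ~ N(root·1, rate²·C) via an eigendecomposition square
root of C; defaults root 0, rate 1 on unit-height trees.  An exponential
i.i.d. option exists for non-normal covariates.

**Counts (Gaussian copula / NORTA).**  Z ~ MVN(0, R) with R the correlation
matrix obtained by standardizing C to unit diagonal (the quantile transform
requires uniform marginals, which only a correlation-scale latent variable
provides); Uᵢ = Φ(Zᵢ); yᵢ = F⁻¹(Uᵢ) with F the Poisson or NB2 CDF at the
target mean (and dispersion).  Marginals are exact by construction;
dependence is phylogeny-induced and monotone in the latent correlations.
Where scipy's discrete quantile search fails (means beyond ~10¹⁵ or extreme
tail uniforms) the count is taken as max(0, round(μ + √V·z)), the normal
approximation through the same latent draw.  Zero-depth tips have no
Brownian variance and are assigned zero latent correlation.

**Tree generators** (all unit height): Kingman-style coalescent
(exchangeable pairwise merging, Exp(k(k−1)/2) waiting times, rescaled),
balanced (equal-depth nested splits, n a power of 2), pectinate "left" tree
(each split isolates one tip; split depths equally spaced), and star.

## The recovery study

`run_sim_study` crosses tree shapes {coalescent, balanced, left, star} with
taxa counts {16, 32, 64, 128}; per replicate it draws x, forms the family
means at the true coefficients (defaults (3, 5), NB2 r = 10.68), draws
counts through the copula, and fits the phylogenetic GEE initialized at the
independent MLE; 1000 replicates per cell by default, mean and SD over
converged replicates, everything reproducible from a single seed.  Design
choices that required judgment:

* **Degenerate replicates.**  Unit-height trees put most means below e³ and
  a strongly correlated covariate can push the whole response to (near) all
  zeros at once.  With fewer than p+2 positive counts the p+1 parameters are
  not identifiable and the estimating-equation root is arbitrary; such
  replicates are tallied per cell (`n_degenerate`) instead of being fit.
  Without the screen a handful of such replicates (1–3%) moved cell means
  by up to an order of magnitude more than the Monte-Carlo error.
* **Coalescent trees are redrawn each replicate.**  Conditioning a whole
  cell on a single random genealogy makes the cell SD a property of that
  one draw (a deep two-clade genealogy halves the effective sample size),
  which destroys the expected monotone decline of the SD in n.  Averaging
  over genealogies restores it.  Deterministic topologies are fixed per cell.
* **Canonical-link NB2 domain.**  The mean is undefined where η ≥ 0, yet
  the default truth (3, 5) with a mean-zero covariate puts η above 0 with
  high probability per tip.  The covariate is redrawn until the whole
  predictor is in-domain, up to a cap (default 200); replicates exhausting
  the cap are counted as domain failures.  On trees with many weakly
  correlated tips the acceptance probability is effectively zero, so the
  NB2 grid is only meaningful at small n — which matches the wide, erratic
  dispersion the NB2 study is expected to show, and is why its cells are
  validated qualitatively (estimates bracket the truth with large SDs,
  failures logged) rather than numerically.

## Bootstrap

Parametric: responses are simulated from the fitted family at the fitted
means — through the copula with C for phylogenetic fits, with independent
marginals for GLM fits — and the same estimator is refit; B = 1000 and a
95% percentile interval by default.  Case resampling is deliberately not
offered: tips are not exchangeable under phylogenetic dependence, and
resampling rows would break C.  Replicate failures are counted, never
imputed.  Reported as bootstrap mean (bootstrap SD), matching the
convention used for the empirical tables.

## What the synthetic data does and does not show

The generator reproduces the study's own conditions: exact marginals, BM
covariates, known C, no measurement error, no within-species replication,
and a correctly specified mean model.  Passing the recovery and
star-equivalence tests therefore demonstrates internal consistency of the
estimating equations and solver — not robustness to misspecified C (wrong
tree, non-BM evolution), missing covariates, or real overdispersion
mechanisms beyond NB2.  The copula's count dependence is also somewhat
weaker than the latent normal correlation (a known property of NORTA for
discrete marginals), so the working covariance overstates dependence
slightly at high correlations; this is part of what the recovery study
exercises.

## Numerical details and edge cases

* Newick input requires branch lengths on every edge; internal labels are
  ignored; duplicate tips, negative lengths, malformed strings are rejected
  with a message naming the problem.
* Tip order of C follows the trait table after alignment, never the newick
  file, to prevent silent misalignment; permuting rows of (Y, X, C) jointly
  leaves estimates unchanged.
* Non-ultrametric trees are accepted for fitting (C is well defined); the
  generators emit ultrametric trees only.
* AICc requires n > k+1 and errors otherwise; Akaike weights are invariant
  to adding a constant to all AICc values.
* Rank-deficient C (e.g. duplicated tips at zero distance) routes W through
  the pseudo-inverse and reports it.
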