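# Methods

This note records the statistical model, the numerical choices behind each
estimator, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one defensible option existed.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and estimands

Provider *i* contributes a binomial count `Y_i ~ Binomial(n_i, p_i)`; the
latent probabilities `p_i` are i.i.d. from a population law `F_p` with
density `f_p`, mean `mu_p` and variance `sigma_p^2`.  Inference is
population-level: the observed providers are treated as a sample from a
larger universe, and `sigma_p^2`/`f_p` are the targets.  (The finite-
population variance of the observed providers is available trivially as
`population_variance` of any vector of values; the package does not pursue
finite-population inference further.)

Patient-level covariates, case-mix adjustment and multivariate adjustment
(for example jointly with provider volume) are out of scope.

## Small-site filtering

Recovering `f_p` from counts is a deconvolution problem; as `n_i` shrinks,
noise-to-signal explodes and the nonparametric estimators degrade before the
parametric one does.  `filter_small_sites` drops `n_i < min_n` with
`min_n = 10` by default (adequate for the adjustment estimators here);
`min_n = 25` mimics the ad hoc exclusion convention common in clinical
reports.  A median retained size below `min_median_n = 20` triggers a
warning only — it flags conditions where density estimation is fragile.
Excluded provider/patient fractions are logged for bookkeeping and carry no
semantics.

## Raw proportions

Variance uses the 1/N divisor, matching the population-moment definition of
the estimand (at N >= 100 the distinction from 1/(N-1) is negligible).  The
KDE is a Gaussian kernel with the rule-of-thumb bandwidth
`h = 0.9 * min(sd, IQR/1.34) * N^(-1/5)` (sd with the N-1 divisor), written
out explicitly rather than delegated to any particular library default, on
a 512-point grid spanning `[min - 3h, max + 3h]`.  The grid may spill
slightly outside [0, 1]; no truncation or renormalisation is applied by
default because either would bias the recorded moments — the estimate
records its actual grid, and an optional reflect-at-boundaries mode exists
for display purposes.  Consequently the KDE's own CDF is not exactly 0/1 at
the interval ends (the EDF, which the bundled raw estimate uses as its CDF,
is).

Expected behaviour, verified by simulation tests: the raw variance estimates
`sigma_p^2 + mean_i E[p_i(1-p_i)]/n_i`, i.e. it is over-dispersed by the
average sampling variance.

## Gaussian hierarchical model

`logit(p_i) = beta0 + b_i`, `b_i ~ N(0, sigma_b^2)`.  The marginal
likelihood integrates `b_i` out per provider with *adaptive* Gauss–Hermite
quadrature: the integrand is re-centred at the conditional mode (found by a
vectorised, globally convergent Newton iteration on a strictly concave
objective) and re-scaled by the curvature there; 25 nodes are then ample
even at `n_i = 20`.  Optimisation is Nelder–Mead over `(beta0, log
sigma_b)` from a method-of-moments start with one jittered restart —
a two-parameter surface where robustness matters more than speed.  A
boundary solution `sigma_b ~ 0` is a legitimate fit (no detectable
heterogeneity), not an error.

Given the fit, the law of `p = expit(beta0 + sigma_b Z)` is logit-normal
and is used in closed form: density
`phi((logit(u)-beta0)/sigma_b) / (sigma_b u(1-u))`, CDF by the probit
transform, variance by Gauss–Hermite with node-doubling from 101 nodes to a
1e-8 relative tolerance.  (Simulating many draws and smoothing them — a
common implementation device — converges to exactly this closed form; using
the analytic object removes that simulation noise.)  Empirical-Bayes
predictions are posterior *means* under the fitted prior, each by adaptive
Gauss–Hermite; the posterior mode is available as an option since software
conventions differ.  Their cross-provider variance is deliberately reported
as the over-shrunk comparator, not as a recommended estimator.

## Moment-adjusted imputation

`W_i = p_hat_i` is modelled as `X_i + U_i` with `U_i ~ N(0, sigma_u2_i)`
and the plug-in `sigma_u2_i = p_hat_i(1-p_hat_i)/n_i`, treated as known.
At the boundary (`y = 0` or `y = n`) the plug-in would be exactly zero —
silently declaring those sites noiseless — so the variance plug-in (only)
substitutes the continuity-corrected `(y+0.5)/(n+1)`; `W_i` itself stays
`y_i/n_i`.

Unbiased latent-moment estimates under normal additive error are

    m1 = mean(W),  m2 = mean(W^2 - s),  m3 = mean(W^3 - 3Ws),
    m4 = mean(W^4 - 6W^2 s + 3 s^2),          s = sigma_u2_i,

validated in the tests against an exact-moments Monte Carlo oracle.  The
adjusted values minimise `sum (W_i - X_i)^2` subject to
`N^-1 sum X_i^r = m_r`, r = 1..M, solved by Newton–Raphson on the joint
stationarity system in `(X, Lambda)` with step-halving and up to five
jittered restarts; the Jacobian's arrow structure (diagonal X-block plus M
border rows/columns) is solved through its Schur complement in O(N M^2) per
iteration, so a fit costs milliseconds inside the Monte Carlo study.
Numerically the system is posed in a centered/standardised power basis
`Z = (X - m1)/sqrt(m2 - m1^2)`: the raw basis `(1, X, X^2, X^3)` is so
collinear on a narrow proportion range that the multipliers explode and
Newton stalls; the reported multipliers are mapped back to the raw basis,
where they satisfy the stationarity identity to the same tolerance.
Convergence is declared at a max residual of 1e-10; the moment constraints
then hold to well below the 1e-8 contract.

Two degeneracies are handled explicitly rather than papered over:

* **Noise exceeds signal** — if `m2 - m1^2 <= 0`, the between-provider law
  is not identifiable from these data and a `NumericalError` is raised.
* **Infeasible higher moments** — every distribution satisfies
  `kurtosis >= skewness^2 + 1` (equality only for two-point laws).  The
  corrected standardized third/fourth moments are extremely noisy when the
  signal variance is far below the sampling variance, and routinely land
  outside this feasible region; no adjusted data set can then match all
  four moments, and pushing Newton toward the boundary produces exactly the
  "mass on a few discrete points" pathology known for this method at small
  site sizes.  `mai_adjust` detects the violation up front and raises
  `InfeasibleMomentsError`; `mai_estimate` falls back to `M = 2` with a
  warning and records the fallback.  The variance estimate is unchanged by
  construction (`m2 - m1^2` either way); only skewness/kurtosis matching is
  given up.  M = 4 remains the default and is used whenever feasible.

With `M = 2` the solution has the affine closed form
`m1 + b (W - mean(W))`, `b = sqrt((m2 - m1^2)/var(W))`, used as an
independent oracle in the tests (it implies rank preservation and variance
contraction).  Adjusted values may fall slightly outside [0, 1]; clipping
would bias the matched moments, so none is applied and the fraction outside
is recorded.

A note on bias: because `E[p_hat(1-p_hat)] = p(1-p)(1-1/n)`, the printed
plug-in under-corrects the second moment by `E[p(1-p)]/n^2` on average.
This second-order term is invisible at large `n_i` but measurable when
`sigma_p^2` is very small (it is about a tenth of the estimand at
`n_i = 30`, `sigma_b^2 = 0.05`); the tests assert the exact expectation,
and the estimator stays comfortably inside the near-unbiased band used in
the study comparisons.

## Smoothing by roughening

The mixing distribution is discretised at `M = 500` midpoints of
equal-width bins of [0, 1] (midpoints keep the binomial likelihood off the
degenerate boundary; 500 points resolve densities far below the visual
scale of interest while keeping the N x M likelihood matrix small).  From
uniform starting weights, each EM step averages the per-provider posterior
over the grid.  The likelihood matrix is computed once in log space,
row-shifted by its maximum to prevent underflow (the shift cancels in the
EM ratio and is restored in the reported log-likelihood), and reused across
iterations — results are identical to naive recomputation.

Run to convergence the recursion yields the nonparametric MLE, which is
discrete and under-dispersed; the estimator of interest stops early.  The
default `nu_N = 50` follows the selection used in the provider-profiling
evaluation this package reproduces; classical guidance ranges from `N/3` to
`2N` and no stopping point is universally best, so *all* iterates (and
their marginal log-likelihoods, which are checked to be nondecreasing — an
EM guarantee) are retained for sensitivity plots, with a `keep_every`
thinning option for very long runs.  On a 3-provider toy the support
collapse that marks convergence completes by roughly 2e4 iterations, after
which the iterate agrees with an independently coded EM fixed point to
total-variation distance below 1e-6 — the basis of the NPML cross-check in
the tests.

## Dirichlet-process beta-binomial mixture

The prior is `p_i ~ F`, `F ~ DP(alpha, Beta(a1, b1))` with `a1 = b1 = 1`
(uniform base) by default.  Conjugacy allows the cluster probabilities to
be integrated out exactly, so the sampler is collapsed Gibbs on the
partition: provider *i* joins cluster *c* with probability proportional to
`n_{-i,c}` times the beta-binomial predictive of `y_i` given the cluster's
other members, or opens a new cluster proportionally to `alpha` times the
prior predictive.  Collapsing makes each update exact and mixes faster than
samplers that carry cluster parameters; posterior functionals are identical
in distribution.  With a Gamma hyper-prior, `alpha` is refreshed once per
sweep by the standard auxiliary-variable (beta-augmentation) update.

**Parameterisation.**  The Gamma hyper-prior uses the *rate*
parameterisation: `alpha ~ Gamma(shape a0, rate b0)`, prior mean `a0/b0`.
This is interoperability-critical: the smoothness preset `(10, 0.10)` then
has prior mean alpha = 100 and puts its central 95% prior mass for N = 100
providers on roughly 52–83 clusters, matching the published calibration;
the scale parameterisation would not.  Presets: DP-1 `Gamma(4, 4)`
(roughness), DP-2 `Gamma(10, 0.10)` (smoothness), DP-3 fixed `alpha = 20`.

`prior_cluster_distribution` performs that calibration by direct CRP
simulation, marginalising over the hyper-prior.  It exploits the sequential
representation — customer *i* opens a new table independently with
probability `alpha/(alpha + i - 1)` — so the cluster count is a sum of
independent Bernoullis and 20,000 draws take milliseconds.  The reported
central 2.5–97.5 percentile interval is used for the 95% prior-mass
statement; an HPD region would differ slightly for these skewed counts.

The posterior density is Rao-Blackwellised: for each retained draw the
conditional predictive is an explicit mixture of Beta densities
(`alpha/(alpha+N)` on the base plus `n_c/(alpha+N)` on each updated
cluster), averaged over draws; mean and variance are the exact integrals of
that averaged density, computed from the Beta component moments.  MCMC
defaults (`n_iter = 5000`, `burn_in = 1000`, `thin = 4`) are sized for desk
runs at N <= 500 and fully configurable; all draws are reproducible from
the config seed.  Non-conjugate base measures and slice/retrospective
samplers are out of scope.

## Synthetic scenarios

Random effects on the logit scale, always standardised to mean 0 and
variance `sigma_b^2` (presets 0.05 and 0.50):

* normal: `N(0, sigma_b^2)`;
* chi-square: `sigma_b (V - 1)/sqrt(2)`, `V ~ chi2(1)` — skewness
  `2 sqrt(2)`, support bounded below at `-sigma_b/sqrt(2)` (the exact
  density returns 0 beyond the bound rather than erroring);
* bimodal: equal mixture of `N(-delta, tau^2)` and `N(+delta, tau^2)` with
  `delta = 2 tau` and `delta^2 + tau^2 = sigma_b^2`.  The source evaluation
  says only "a bimodal mixture of normals"; this separation ratio gives two
  clearly resolved modes and is recorded as this package's choice — results
  that depend on the exact mixture geometry are treated as properties, not
  reproduced values.

The intercept is `beta0 = logit(0.25)` by default, a typical early-
follow-up rate in the motivating cardiovascular registries (the source does
not print its value; it is configurable).  Probabilities are
`expit(beta0 + b)`; outcomes are binomial.

Site-size profiles: fixed 20 or 30; otherwise rounded lognormals truncated
at `n >= 10` by rejection, calibrated so the quartiles of the discretised,
truncated law hit the published summaries — trial-like
`(mu, sigma) = (3.1038, 0.8125)` for median ≈ 25, IQR ≈ 17–43; registry-like
`(4.1874, 0.9367)` for median ≈ 65, IQR ≈ 38–126.  The generator matches
those three quantiles, not any full histogram (the source's size histograms
are not published); real registries also correlate size with performance,
which the generator does not emulate — passing tests therefore support the
estimators under independent sizes only.

Exact truth accessors (`true_density`, `true_cdf`, `true_variance`) use the
closed-form logit-normal components where available and adaptive quadrature
(relative tolerance ~1e-8) for moments, so estimator error is never
measured against a simulated stand-in for the truth.

## Metrics and the study driver

ED-CDF and ED-PDF are integrated squared errors computed by composite
Simpson on a fixed 2001-point grid over [0, 1] (relative error vs 4001
points below 1e-4); a fixed grid is used deliberately because the step
discontinuities of empirical CDFs defeat adaptive quadrature error
estimators.  When an estimate's grid spills outside [0, 1], the ED-PDF
integration range extends to cover it with the true density set to 0 —
spill-over mass is penalised, not ignored.

`run_study` derives per-replicate child seeds counter-style
(`default_rng([base_seed, b])`), so all methods see identical datasets — a
paired design that sharpens method contrasts and makes reports reproducible
bit-for-bit.  Replicate-level failures (for example the MAI noise-exceeds-
signal error at near-zero true variance) are recorded and excluded from that
method's aggregates; a method failing more than 10% of replicates has its
column marked invalid rather than silently averaged.  The default
replication in tests is B = 200, sized for desk-scale runs; tolerances on
stochastic checks are stated as multiples of the Monte Carlo standard error
at that B.  Variance results are also reported as ratios to the true
variance, the scale on which over- and under-dispersion are compared across
scenarios.

The DP samplers are the one family too slow (pure-Python Gibbs over
hundreds of providers times hundreds of replicates) for full-replication
study runs; they are validated instead by exact small-N partition
enumeration, prior-recovery of the CRP cluster-count law, and single-dataset
sanity checks, and can be included in `run_study` with reduced MCMC
settings via `dp_mcmc`.

## Known limitations

* The MAI error model is normal while binomial error is skewed at small
  `n_i`; together with the plug-in bias noted above this is the main
  accuracy limit at very small sites.
* The M = 2 fallback sacrifices skewness/kurtosis matching exactly in the
  regime where higher moments are least estimable; users who need shape
  fidelity there need larger sites, not a different switch.
* SBR's stopping index trades smoothness against dispersion and no
  data-driven rule is provided, by design; inspect the stored trajectory.
* KDE spill-over means raw/MAI density mass slightly outside [0, 1] is
  possible and is scored against a zero truth there.
* The CLI's `study` command exposes the same driver as the library; very
  large B with DP methods enabled is not a supported desk workload.
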