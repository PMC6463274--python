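"""Gaussian hierarchical (random-intercept logistic) model.

The model puts a normal law on the logit of the provider probability:
``logit(p_i) = beta0 + b_i`` with ``b_i ~ Normal(0, sigma_b2)``.  The
marginal likelihood integrates the random intercept out of each provider's
binomial likelihood; the integrals are evaluated by adaptive Gauss-Hermite
quadrature, re-centred at each provider's conditional mode and re-scaled by
the curvature there, which keeps a 25-node rule accurate even for small
``n_i``.  Fitting maximises the marginal likelihood over (beta0, log sigma_b)
with a derivative-free simplex from a method-of-moments start.

Once fitted, the implied law of ``p = expit(beta0 + sigma_b Z)`` is
logit-normal and every summary is available in closed form or by one-
dimensional quadrature: `ghm_density` evaluates the exact logit-normal
density/CDF, `ghm_variance` the exact variance of p, and `eb_predictions`
the per-provider empirical-Bayes posterior means (included as the classic
over-shrunk comparator, not as a recommended variance estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logit, gammaln, logsumexp
from scipy.stats import norm

from .cohort import ProviderCounts
from .exceptions import ConvergenceError, ValidationError
from .raw import DistributionEstimate, kde, population_variance

__all__ = ["GHMFit", "fit_ghm", "ghm_density", "ghm_variance", "eb_predictions"]

# below this random-effect SD the model is treated as degenerate
_SIGMA_FLOOR = 1e-4


@dataclass(frozen=True)
class GHMFit:
    """Fitted random-intercept logistic model.

    ``beta0`` is the intercept on the logit scale, ``sigma_b`` the
    random-effect SD, ``loglik`` the maximised marginal log-likelihood and
    ``n_quad`` the Gauss-Hermite rule size used per provider.
    """

    beta0: float
    sigma_b: float
    loglik: float
    n_quad: int = 25
    converged: bool = True

    @property
    def sigma_b2(self) -> float:
        return self.sigma_b**2


def _conditional_modes(beta0, sigma_b, y, n, iters=60):
    """Vectorised Newton search for the mode of b -> log f(y|b) + log phi(b/s).

    Works on the standardised scale z = b / sigma_b; the integrand
    g(z) = y*log p + (n-y)*log(1-p) + log phi(z), p = expit(beta0 + sigma_b z),
    is strictly concave, so Newton converges fast from z = 0.
    """
    z = np.zeros_like(y, dtype=float)
    for _ in range(iters):
        p = expit(beta0 + sigma_b * z)
        grad = sigma_b * (y - n * p) - z
        hess = -(sigma_b**2) * n * p * (1 - p) - 1.0
        step = grad / hess
        z = z - step
        if np.max(np.abs(step)) < 1e-12:
            break
    p = expit(beta0 + sigma_b * z)
    curv = (sigma_b**2) * n * p * (1 - p) + 1.0  # -g''(z*)
    return z, 1.0 / np.sqrt(curv)


def marginal_loglik(beta0: float, sigma_b: float, counts: ProviderCounts,
                    n_quad: int = 25) -> float:
    """Marginal log-likelihood with the binomial coefficient included."""
    y = counts.y.astype(float)
    n = counts.n.astype(float)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    if sigma_b <= 0:
        eta = beta0
        ll = const + y * log_expit(eta) + (n - y) * log_expit(-eta)
        return float(ll.sum())
    zhat, tau = _conditional_modes(beta0, sigma_b, y, n)
    z = zhat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    eta = beta0 + sigma_b * z
    g = (
        y[:, None] * log_expit(eta)
        + (n - y)[:, None] * log_expit(-eta)
        + norm.logpdf(z)
    )
    ll_i = (
        const
        + np.log(np.sqrt(2.0) * tau)
        + logsumexp(g + nodes[None, :] ** 2 + np.log(weights)[None, :], axis=1)
    )
    return float(ll_i.sum())


def _moment_start(counts: ProviderCounts) -> tuple[float, float]:
    p_tilde = (counts.y + 0.5) / (counts.n + 1.0)
    l = logit(p_tilde)
    beta0 = float(np.log(counts.y.sum() + 0.5) - np.log(counts.n.sum() - counts.y.sum() + 0.5))
    # crude deconvolution of the logit-scale sampling noise ~ 1/(n p (1-p))
    noise = np.mean(1.0 / (counts.n * p_tilde * (1 - p_tilde)))
    s2 = max(float(np.var(l) - noise), 1e-3)
    return beta0, s2


def fit_ghm(counts: ProviderCounts, n_quad: int = 25) -> GHMFit:
    """Maximum marginal likelihood fit of (beta0, sigma_b).

    Optimises over (beta0, log sigma_b) by Nelder-Mead with one jittered
    restart on failure.  A boundary solution sigma_b ~ 0 is a valid result
    (no detectable heterogeneity), not an error.
    """
    if counts.N < 2:
        raise ValidationError("fit_ghm requires at least two providers")

    def objective(theta):
        return -marginal_loglik(theta[0], np.exp(theta[1]), counts, n_quad)

    beta0_0, s2_0 = _moment_start(counts)
    x0 = np.array([beta0_0, 0.5 * np.log(s2_0)])
    best = None
    for attempt in range(2):
        start = x0 if attempt == 0 else x0 + np.array([0.3, 0.7])
        res = minimize(objective, start, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            best = res if res.fun <= best.fun else best
            break
    beta0, sigma_b = float(best.x[0]), float(np.exp(best.x[1]))
    fit = GHMFit(beta0=beta0, sigma_b=sigma_b, loglik=float(-best.fun),
                 n_quad=n_quad, converged=bool(best.success))
    if not (best.success and np.isfinite(best.fun)):
        raise ConvergenceError("GHM fit did not converge", best=fit)
    return fit


def _default_grid(grid_size: int = 512) -> np.ndarray:
    eps = 1e-6
    return np.linspace(eps, 1 - eps, grid_size)


def ghm_density(fit: GHMFit, grid=None) -> DistributionEstimate:
    """Exact logit-normal density/CDF implied by the fit.

    ``f(u) = phi((logit(u) - beta0)/sigma_b) / (sigma_b u (1-u))`` — the
    analytic limit of simulating a large number of logit-normal draws and
    smoothing them.  A boundary fit (sigma_b ~ 0) yields a point mass at
    expit(beta0); the result is then flagged ``degenerate`` with a step CDF
    and zero density.
    """
    if grid is None:
        grid = _default_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValidationError("ghm_density grid must lie strictly inside (0, 1)")
    mu, sd = fit.beta0, fit.sigma_b
    center = float(expit(mu))
    if sd < _SIGMA_FLOOR:
        def _cdf_step(x):
            x = np.asarray(x, dtype=float)
            return (x >= center).astype(float)

        return DistributionEstimate(
            method="ghm", mean=center, variance=0.0, grid=grid,
            pdf=np.zeros_like(grid), cdf=_cdf_step,
            extras={"beta0": mu, "sigma_b2": sd**2, "degenerate": True},
        )
    pdf = norm.pdf((logit(grid) - mu) / sd) / (sd * grid * (1 - grid))

    def _cdf(x):
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, 1e-300, 1 - 1e-16)
        out = norm.cdf((logit(xc) - mu) / sd)
        out = np.where(x <= 0, 0.0, out)
        return np.where(x >= 1, 1.0, out)

    mean = _probability_moment(fit, 1)
    return DistributionEstimate(
        method="ghm", mean=mean, variance=ghm_variance(fit), grid=grid, pdf=pdf,
        cdf=_cdf,
        extras={"beta0": mu, "sigma_b2": sd**2, "n_quad": fit.n_quad,
                "loglik": fit.loglik, "degenerate": False},
    )


def _probability_moment(fit: GHMFit, power: int, n_nodes: int = 101) -> float:
    """E[expit(beta0 + sigma_b Z)**power] by Gauss-Hermite, node-doubling."""
    prev = None
    n = n_nodes
    for _ in range(8):
        x, w = np.polynomial.hermite.hermgauss(n)
        val = float(np.sum(w * expit(fit.beta0 + fit.sigma_b * np.sqrt(2) * x) ** power)
                    / np.sqrt(np.pi))
        if prev is not None and abs(val - prev) <= 1e-8 * max(abs(val), 1e-12):
            return val
        prev = val
        n = 2 * n + 1
    return prev


def ghm_variance(fit: GHMFit) -> float:
    """Var[expit(beta0 + sigma_b Z)] under the fitted logit-normal law."""
    if fit.sigma_b == 0:
        return 0.0
    m1 = _probability_moment(fit, 1)
    m2 = _probability_moment(fit, 2)
    return max(m2 - m1**2, 0.0)


def eb_predictions(fit: GHMFit, counts: ProviderCounts,
                   posterior: str = "mean") -> DistributionEstimate:
    """Per-provider empirical-Bayes predictions under the fitted prior.

    ``p_hat_b_i = E[expit(beta0 + sigma_b Z) | y_i]`` by adaptive
    Gauss-Hermite (``posterior="mode"`` returns the posterior mode on the
    probability scale instead).  The predictions are deliberately over-shrunk
    as a population-spread summary: their 1/N variance understates the true
    between-provider variance.
    """
    y = counts.y.astype(float)
    n = counts.n.astype(float)
    mu, sd = fit.beta0, fit.sigma_b
    if sd < _SIGMA_FLOOR:
        preds = np.full(counts.N, float(expit(mu)))
    elif posterior == "mode":
        zhat, _ = _conditional_modes(mu, sd, y, n)
        preds = expit(mu + sd * zhat)
    else:
        nodes, weights = np.polynomial.hermite.hermgauss(fit.n_quad)
        zhat, tau = _conditional_modes(mu, sd, y, n)
        z = zhat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
        eta = mu + sd * z
        logw = (
            y[:, None] * log_expit(eta)
            + (n - y)[:, None] * log_expit(-eta)
            + norm.logpdf(z)
            + nodes[None, :] ** 2
            + np.log(weights)[None, :]
        )
        logw -= logsumexp(logw, axis=1, keepdims=True)
        preds = np.sum(np.exp(logw) * expit(eta), axis=1)
    if np.ptp(preds) < 1e-12:
        # full shrinkage: KDE undefined, return a degenerate summary
        center = float(preds.mean())

        def _cdf_step(x):
            return (np.asarray(x, dtype=float) >= center).astype(float)

        return DistributionEstimate(
            method="ghm_eb", mean=center, variance=0.0,
            grid=np.asarray([center]), pdf=np.asarray([0.0]), cdf=_cdf_step,
            support_points=preds, extras={"degenerate": True},
        )
    smooth = kde(preds)
    return DistributionEstimate(
        method="ghm_eb",
        mean=float(preds.mean()),
        variance=population_variance(preds),
        grid=smooth.grid,
        pdf=smooth.pdf,
        cdf=smooth.cdf,
        support_points=preds,
        extras={"bandwidth": smooth.extras["bandwidth"], "posterior": posterior},
    )
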