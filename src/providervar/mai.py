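"""Moment-adjusted imputation (MAI) for provider proportions.

The raw proportion is viewed as a noisy measurement of the latent provider
probability: ``W_i = X_i + U_i`` with approximately normal sampling error
``U_i`` of known variance ``sigma_u2_i = p_hat_i (1 - p_hat_i) / n_i``.
Deconvolution corrections under normal additive error give unbiased
estimates ``m_r`` of the first M moments of X; the adjusted values are then
the solution of a constrained least-displacement problem

    minimise  sum_i (W_i - X_i)^2
    subject to  N^-1 sum_i X_i^r = m_r,   r = 1..M,

solved by Newton-Raphson on the joint stationarity system in the adjusted
values and the M Lagrange multipliers.  By construction the first M sample
moments of the adjusted values unbiasedly estimate the latent moments — in
particular their 1/N variance is an unbiased estimate of the
between-provider variance, removing the over-dispersion of the raw
proportions without the over-shrinkage of empirical-Bayes predictions.

Matching M=4 moments (mean, variance, skewness, kurtosis) is the default and
the general recommendation; M=2 suffices for a normal latent law and has an
affine closed form used as an internal cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .cohort import ProviderCounts
from .exceptions import (ConvergenceError, InfeasibleMomentsError,
                         NumericalError, ValidationError)
from .raw import DistributionEstimate, edf, kde, population_variance, raw_proportions

__all__ = [
    "MAIResult",
    "error_variances",
    "unbiased_moments",
    "mai_adjust",
    "mai_estimate",
]

_RESID_TOL = 1e-10
_MAX_ITER = 200
_MAX_RESTARTS = 5


@dataclass(frozen=True)
class MAIResult:
    """Output of the constrained moment-matching adjustment.

    ``adjusted`` are the displaced values; ``multipliers`` the Lagrange
    multipliers of the M moment constraints; ``target_moments`` the unbiased
    moment estimates the constraints enforce; ``max_constraint_violation``
    the largest residual moment error at the solution.
    """

    adjusted: np.ndarray
    multipliers: np.ndarray
    target_moments: np.ndarray
    M: int
    error_variances: np.ndarray
    iterations: int
    max_constraint_violation: float


def error_variances(counts: ProviderCounts) -> np.ndarray:
    """Per-provider sampling-error variances ``p(1-p)/n``.

    The plug-in uses the raw proportion except at the boundary (y = 0 or
    y = n), where the continuity-corrected ``(y + 0.5)/(n + 1)`` is
    substituted so no site is treated as noiseless; the measured value W
    itself is left at y/n.
    """
    p_hat = raw_proportions(counts)
    p_tilde = p_hat.copy()
    boundary = (counts.y == 0) | (counts.y == counts.n)
    p_tilde[boundary] = (counts.y[boundary] + 0.5) / (counts.n[boundary] + 1.0)
    return p_tilde * (1 - p_tilde) / counts.n


def unbiased_moments(W, sigma_u2, M: int) -> np.ndarray:
    """Deconvolution-corrected moment estimates of the latent variable.

    Under W = X + U, U ~ Normal(0, sigma_u2) independent of X, each
    per-observation summand below has expectation E[X^r]:

        r=1: W
        r=2: W^2 - s
        r=3: W^3 - 3 W s
        r=4: W^4 - 6 W^2 s + 3 s^2        (s = sigma_u2_i)

    (the Hermite-polynomial corrections for normal additive error).
    """
    W = np.asarray(W, dtype=float)
    s = np.asarray(sigma_u2, dtype=float)
    if W.shape != s.shape:
        raise ValidationError("W and sigma_u2 must have equal length")
    if not 1 <= M <= 4:
        raise ValidationError("M must be in 1..4")
    summands = [W, W**2 - s, W**3 - 3 * W * s, W**4 - 6 * W**2 * s + 3 * s**2]
    return np.array([summands[r].mean() for r in range(M)])


def _transformed_targets(m_hat, c, sc, M):
    """Targets for the standardized moments N^-1 sum ((X-c)/sc)^r.

    Matching the raw moments m_1..m_M is equivalent to matching these (the
    map between the two moment sets is triangular and invertible)."""
    m_full = np.concatenate([[1.0], m_hat])       # m_0 = 1
    mu = np.empty(M)
    for r in range(1, M + 1):
        ks = np.arange(r + 1)
        mu[r - 1] = np.sum(
            comb(r, ks) * m_full[ks] * (-c) ** (r - ks)
        ) / sc**r
    return mu


def _raw_multipliers(lam, c, sc, M):
    """Re-express sum_r lam_r Z^{r-1} (Z = (X-c)/sc) in the raw power basis,
    so the reported multipliers satisfy X - W + sum_r lam_raw_r X^{r-1} = 0."""
    out = np.zeros(M)
    for r in range(1, M + 1):
        q = r - 1
        for k in range(q + 1):
            out[k] += lam[r - 1] * comb(q, k) * (-c) ** (q - k) / sc**q
    return out


def _newton_solve(W, m_hat, X0, M, rng):
    """Newton-Raphson on the stationarity system of the constrained problem.

    Unknowns (X_1..X_N, lambda_1..lambda_M); residuals
        F_i = X_i - W_i + sum_r lambda_r Z_i^{r-1},   Z = (X - c)/sc,
        G_r = N^-1 sum_i Z_i^r - mu_r,
    an equivalent restatement of the raw-moment system in a centered and
    standardized power basis (c = m_1, sc = sqrt(m_2 - m_1^2)) — the raw
    basis (1, X, X^2, X^3) is so collinear on a narrow proportion range that
    the multipliers explode and Newton stalls.  The Jacobian has arrow
    structure (diagonal X-block plus M border rows/columns) and is solved
    through its Schur complement in O(N M^2) per iteration.
    """
    N = W.size
    c = m_hat[0]
    sc = np.sqrt(m_hat[1] - m_hat[0] ** 2) if M >= 2 else max(W.std(), 1e-6)
    mu = _transformed_targets(m_hat, c, sc, M)
    X = X0.copy()
    lam = np.zeros(M)
    powers = np.arange(M)

    def residuals(X, lam):
        Z = (X - c) / sc
        P = Z[:, None] ** powers[None, :]          # Z^{r-1}, r=1..M
        F = X - W + P @ lam
        G = np.array([(Z ** (r + 1)).mean() for r in range(M)]) - mu
        return F, G

    F, G = residuals(X, lam)
    norm0 = max(np.max(np.abs(F)), np.max(np.abs(G)))
    for it in range(1, _MAX_ITER + 1):
        if norm0 <= _RESID_TOL:
            return X, _raw_multipliers(lam, c, sc, M), it - 1, norm0
        Z = (X - c) / sc
        P = Z[:, None] ** powers[None, :]
        # d = dF_i/dX_i = 1 + sum_{r>=2} lambda_r (r-1) Z^{r-2} / sc
        d = np.ones(N)
        for r in range(2, M + 1):
            d += lam[r - 1] * (r - 1) * Z ** (r - 2) / sc
        if np.any(np.abs(d) < 1e-12):
            raise NumericalError("singular diagonal in Newton system")
        B = P                                       # dF_i/dlam_r
        C = ((powers + 1)[None, :] * P).T / (N * sc)  # dG_r/dX_i
        Dinv_B = B / d[:, None]
        S = -C @ Dinv_B                             # Schur complement
        rhs = -G + C @ (F / d)
        try:
            dlam = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular Schur complement") from exc
        dX = -(F + B @ dlam) / d
        # step-halving line search on the max-residual norm
        step = 1.0
        for _ in range(50):
            Xn, ln = X + step * dX, lam + step * dlam
            Fn, Gn = residuals(Xn, ln)
            nn = max(np.max(np.abs(Fn)), np.max(np.abs(Gn)))
            if (nn < norm0 and np.isfinite(nn)) or norm0 <= _RESID_TOL:
                break
            step *= 0.5
        if not np.isfinite(nn) or nn >= norm0:
            raise NumericalError("Newton line search stalled")
        X, lam, F, G, norm0 = Xn, ln, Fn, Gn, nn
    if norm0 <= _RESID_TOL:
        return X, _raw_multipliers(lam, c, sc, M), _MAX_ITER, norm0
    raise NumericalError("Newton did not reach tolerance")


def mai_adjust(W, sigma_u2, M: int = 4) -> MAIResult:
    """Solve the constrained least-displacement problem for adjusted values.

    Initialised at X = W with zero multipliers, with step-halving and up to
    5 jittered restarts.  Requires the estimated signal variance
    ``m_2 - m_1^2`` to be positive: when sampling noise swamps the
    between-provider signal the latent law is unidentifiable and a
    ``NumericalError`` is raised rather than a spurious adjustment returned.
    """
    W = np.asarray(W, dtype=float)
    s = np.asarray(sigma_u2, dtype=float)
    if W.size <= M:
        raise ValidationError("need more observations than matched moments")
    m_hat = unbiased_moments(W, s, M)
    if M >= 2 and m_hat[1] - m_hat[0] ** 2 <= 0:
        raise NumericalError(
            "noise exceeds estimated signal: corrected variance estimate "
            f"{m_hat[1] - m_hat[0]**2:.3e} <= 0; the provider-level law is "
            "not identifiable from these data"
        )
    if M >= 4:
        margin = _feasibility_margin(m_hat)
        if margin <= 0:
            raise InfeasibleMomentsError(
                "corrected third/fourth-moment targets are infeasible "
                f"(kurtosis - skewness^2 - 1 = {margin:.3f} <= 0); no data "
                "set can match all four moments — rerun with M=2 or use "
                "mai_estimate, which falls back automatically"
            )
    rng = np.random.default_rng(0)
    scale = max(W.std(), 1e-3)
    last_err = None
    for restart in range(_MAX_RESTARTS + 1):
        X0 = W if restart == 0 else W + rng.normal(0, 0.1 * scale, W.size)
        try:
            X, lam, iters, viol = _newton_solve(W, m_hat, X0, M, rng)
            break
        except NumericalError as exc:
            last_err = exc
    else:
        raise ConvergenceError(
            f"MAI Newton solver failed after {_MAX_RESTARTS} restarts: {last_err}"
        )
    result = MAIResult(
        adjusted=X,
        multipliers=lam,
        target_moments=m_hat,
        M=M,
        error_variances=s,
        iterations=iters,
        max_constraint_violation=float(viol),
    )
    _warn_if_collapsed(W, X)
    return result


def _feasibility_margin(m_hat) -> float:
    """Kurtosis minus (skewness^2 + 1) of the target moments.

    Every distribution satisfies kurtosis >= skewness^2 + 1 (equality only
    for two-point laws), so a negative margin means the four corrected
    moments cannot be matched by any adjusted data set.  When sampling noise
    dwarfs the between-provider signal the corrected standardized third and
    fourth moments are extremely noisy and land outside the feasible region
    routinely; attempting to match them anyway drives the adjustment toward
    a two-point collapse (discrete mass) before failing.
    """
    c1 = m_hat[0]
    v = m_hat[1] - c1**2
    c3 = m_hat[2] - 3 * c1 * m_hat[1] + 2 * c1**3
    c4 = m_hat[3] - 4 * c1 * m_hat[2] + 6 * c1**2 * m_hat[1] - 3 * c1**4
    skew = c3 / v**1.5
    kurt = c4 / v**2
    return float(kurt - skew**2 - 1.0)


def _warn_if_collapsed(W: np.ndarray, X: np.ndarray) -> None:
    # rare small-n pathology: adjusted values piling onto a few points.
    # Ties already present in W (binomial discreteness) are not collapse.
    def n_distinct(v):
        return int(np.count_nonzero(np.diff(np.sort(v)) > 1e-6) + 1)

    if n_distinct(X) < 0.8 * n_distinct(W):
        warnings.warn(
            "more than 20% of the distinct input values collapsed onto "
            "near-identical adjusted points; the adjusted density may show "
            "spurious discrete mass",
            stacklevel=3,
        )


def mai_estimate(counts: ProviderCounts, M: int = 4,
                 bandwidth: float | None = None) -> DistributionEstimate:
    """Full MAI pipeline: proportions -> error variances -> adjustment ->
    variance/EDF/KDE of the adjusted values.

    Adjusted values may fall slightly outside [0, 1]; no clipping is applied
    (clipping would bias the matched moments) and the fraction outside is
    recorded in ``extras['frac_outside']``.

    When the corrected third/fourth-moment targets are infeasible or the
    four-moment solve fails — routine when sampling noise dwarfs the
    between-provider signal — the adjustment falls back to matching two
    moments (the variance estimate is identical by construction; only
    shape-matching is given up).  The fallback is recorded in
    ``extras['M_requested']`` / ``extras['fallback_reason']``.
    """
    W = raw_proportions(counts)
    s = error_variances(counts)
    fallback_reason = None
    try:
        res = mai_adjust(W, s, M=M)
    except (InfeasibleMomentsError, ConvergenceError) as exc:
        if M <= 2:
            raise
        fallback_reason = str(exc)
        warnings.warn(
            f"four-moment adjustment unavailable ({exc.__class__.__name__}); "
            "falling back to two matched moments",
            stacklevel=2,
        )
        res = mai_adjust(W, s, M=2)
    X = res.adjusted
    smooth = kde(X, bandwidth=bandwidth)
    frac_outside = float(np.mean((X < 0) | (X > 1)))
    return DistributionEstimate(
        method="mai",
        mean=float(X.mean()),
        variance=population_variance(X),
        grid=smooth.grid,
        pdf=smooth.pdf,
        cdf=edf(X),
        support_points=X,
        extras={
            "M": res.M,
            "M_requested": M,
            "fallback_reason": fallback_reason,
            "bandwidth": smooth.extras["bandwidth"],
            "multipliers": res.multipliers.tolist(),
            "target_moments": res.target_moments.tolist(),
            "max_constraint_violation": res.max_constraint_violation,
            "frac_outside": frac_outside,
            "iterations": res.iterations,
        },
    )
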