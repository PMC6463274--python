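"""Naive estimators of the provider-probability law, and the shared
``DistributionEstimate`` container.

The raw method treats the provider sample proportions ``p_hat_i = y_i / n_i``
as if they were the latent probabilities: their 1/N-divisor sample variance
estimates the between-provider variance, their empirical distribution function
estimates the CDF, and a Gaussian kernel density estimate with the classic
rule-of-thumb bandwidth estimates the density.  Because each proportion
carries binomial sampling error of magnitude ``p(1-p)/n``, the raw variance is
over-dispersed: it estimates the provider variance *plus* the average
sampling-error variance.  The raw machinery is nevertheless reused by the
adjustment methods (moment-adjusted values are summarised with the same
variance/EDF/KDE operations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import ProviderCounts
from .exceptions import ValidationError

__all__ = [
    "DistributionEstimate",
    "raw_proportions",
    "population_variance",
    "rot_bandwidth",
    "kde",
    "edf",
    "raw_estimate",
]


@dataclass
class DistributionEstimate:
    """An estimate of the between-provider probability law.

    Attributes
    ----------
    method : str
        One of ``raw | ghm | ghm_eb | mai | sbr | dp``.
    mean, variance : float
        First two moments of the estimated law.
    grid : ndarray
        Strictly increasing abscissae on which ``pdf`` is tabulated.  Kernel
        estimates may spill slightly outside [0, 1]; the grid records the
        actual support used and no renormalisation is applied.
    pdf : ndarray
        Nonnegative density values on ``grid``.
    cdf : callable
        Vectorised CDF evaluator.
    support_points : ndarray or None
        The raw values the estimate is built from (proportions, adjusted
        values, or empirical-Bayes predictions), when applicable.
    extras : dict
        Method-specific metadata (bandwidth, fitted parameters, warnings...).
    """

    method: str
    mean: float
    variance: float
    grid: np.ndarray
    pdf: np.ndarray
    cdf: Callable[[np.ndarray], np.ndarray]
    support_points: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def pdf_at(self, x) -> np.ndarray:
        """Density interpolated linearly on the tabulation grid, 0 outside."""
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.grid, self.pdf, left=0.0, right=0.0)

    def pdf_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "pdf": self.pdf})

    def summary(self) -> dict:
        out = {"method": self.method, "mean": float(self.mean),
               "variance": float(self.variance)}
        for key, val in self.extras.items():
            if isinstance(val, (int, float, str, bool)) or val is None:
                out[key] = val
        return out

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def raw_proportions(counts: ProviderCounts) -> np.ndarray:
    """Provider sample proportions ``p_hat_i = y_i / n_i``."""
    return counts.proportions()


def population_variance(values) -> float:
    """Sample variance with the 1/N divisor.

    The 1/N (rather than 1/(N-1)) divisor matches the definition of the
    between-provider variance as a population moment; for the provider counts
    encountered in practice (N >= 100) the difference is negligible.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("population_variance of an empty vector")
    return float(np.mean((values - values.mean()) ** 2))


def rot_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb bandwidth ``0.9 * min(sd, IQR/1.34) * N**(-1/5)``.

    ``sd`` uses the N-1 divisor.  This is the classic normal-reference rule
    for a Gaussian kernel; it is written out explicitly so results are
    reproducible without reference to any particular software default.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * values.size ** (-1 / 5)


def kde(
    values,
    bandwidth: float | None = None,
    grid_size: int = 512,
    value_range: tuple[float, float] | None = None,
    reflect: bool = False,
) -> DistributionEstimate:
    """Gaussian kernel density estimate of a set of values.

    The grid spans ``[min - 3h, max + 3h]`` intersected with ``value_range``
    (no restriction by default), on ``grid_size`` points.  With
    ``reflect=True`` mass spilling below 0 or above 1 is folded back at the
    boundaries instead (off by default: the spill-over is small and
    truncation/renormalisation would bias the recorded moments).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("kde requires at least two values")
    if bandwidth is None:
        bandwidth = rot_bandwidth(values)
    if not bandwidth > 0:
        raise ValidationError(
            "kde bandwidth is zero (constant input); pass an explicit bandwidth"
        )
    h = float(bandwidth)
    lo, hi = values.min() - 3 * h, values.max() + 3 * h
    if value_range is not None:
        lo, hi = max(lo, value_range[0]), min(hi, value_range[1])
    grid = np.linspace(lo, hi, grid_size)

    def _pdf(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = norm.pdf((x[:, None] - values[None, :]) / h).mean(axis=1) / h
        if reflect:
            out = out + norm.pdf((x[:, None] + values[None, :]) / h).mean(axis=1) / h
            out = out + norm.pdf(
                ((2 - x)[:, None] - values[None, :]) / h
            ).mean(axis=1) / h
        return out

    def _cdf(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = norm.cdf((x[:, None] - values[None, :]) / h).mean(axis=1)
        if reflect:
            # reflection at 0 and 1 folds tail mass back into [0, 1]
            out = out - norm.cdf((-x[:, None] - values[None, :]) / h).mean(axis=1)
            out = out + (
                norm.cdf(((2 - values)[None, :] - (2 - x)[:, None]) / h).mean(axis=1)
            )
        return np.clip(out, 0.0, 1.0)

    pdf = _pdf(grid)
    mean = float(values.mean())
    var = population_variance(values) + h**2  # exact moments of the KDE itself
    return DistributionEstimate(
        method="raw",
        mean=mean,
        variance=var,
        grid=grid,
        pdf=pdf,
        cdf=_cdf,
        support_points=values,
        extras={"bandwidth": h, "reflect": reflect},
    )


def edf(values) -> Callable[[np.ndarray], np.ndarray]:
    """Empirical distribution function ``F(x) = N^-1 sum 1{v_i <= x}``.

    Right-continuous; ties handled by the <= convention.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValidationError("edf of an empty vector")

    def _cdf(x):
        x = np.asarray(x, dtype=float)
        return np.searchsorted(values, x, side="right") / values.size

    return _cdf


def raw_estimate(counts: ProviderCounts, bandwidth: float | None = None) -> DistributionEstimate:
    """Bundle the naive summaries of the raw proportions.

    Variance is the 1/N-divisor sample variance of the proportions (not of
    the kernel estimate), the CDF is the EDF, and the density the
    rule-of-thumb KDE.
    """
    p_hat = raw_proportions(counts)
    smooth = kde(p_hat, bandwidth=bandwidth)
    return DistributionEstimate(
        method="raw",
        mean=float(p_hat.mean()),
        variance=population_variance(p_hat),
        grid=smooth.grid,
        pdf=smooth.pdf,
        cdf=edf(p_hat),
        support_points=p_hat,
        extras={"bandwidth": smooth.extras["bandwidth"]},
    )
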