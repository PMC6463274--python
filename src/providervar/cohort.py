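"""Provider-level binomial count data: container, I/O and small-site filters.

The data model is the two-stage sampling view of provider profiling: within
provider i, ``n_i`` patients each experience a binary outcome, summing to the
event count ``y_i``; across providers the latent outcome probabilities
``p_i`` follow an unknown population law whose variance and density the
estimator modules recover.  Patient-level 0/1 tables are aggregated to
provider counts at read time; within-provider structure is never modelled.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger("providervar")

__all__ = [
    "ProviderCounts",
    "FilterPolicy",
    "read_counts",
    "write_counts",
    "filter_small_sites",
]


@dataclass(frozen=True)
class ProviderCounts:
    """Observed event counts ``y_i`` out of ``n_i`` patients per provider.

    Attributes
    ----------
    provider_id : ndarray of object
        Unique opaque labels, one per provider.
    y : ndarray of int
        Event counts, ``0 <= y_i <= n_i``.
    n : ndarray of int
        Patients per provider, ``n_i >= 1``.
    """

    provider_id: np.ndarray
    y: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        pid = np.asarray(self.provider_id, dtype=object)
        y = np.asarray(self.y)
        n = np.asarray(self.n)
        if pid.ndim != 1 or y.shape != pid.shape or n.shape != pid.shape:
            raise ValidationError("provider_id, y and n must be equal-length 1-d arrays")
        if pid.size < 1:
            raise ValidationError("at least one provider is required")
        if len(set(pid.tolist())) != pid.size:
            raise ValidationError("duplicate provider_id values")
        for name, arr in (("y", y), ("n", n)):
            if not np.all(np.isfinite(arr.astype(float))):
                raise ValidationError(f"{name} contains non-finite values")
            if np.any(arr.astype(float) != np.round(arr.astype(float))):
                raise ValidationError(f"{name} contains non-integer counts")
        y = y.astype(np.int64)
        n = n.astype(np.int64)
        if np.any(n < 1):
            raise ValidationError("n must be >= 1 for every provider")
        if np.any(y < 0):
            raise ValidationError("y must be >= 0 for every provider")
        if np.any(y > n):
            raise ValidationError("y exceeds n for at least one provider")
        object.__setattr__(self, "provider_id", pid)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n", n)

    @property
    def N(self) -> int:
        """Number of providers."""
        return int(self.y.size)

    def proportions(self) -> np.ndarray:
        """Raw sample proportions ``y_i / n_i``."""
        return self.y / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"provider_id": self.provider_id, "y": self.y, "n": self.n}
        )


@dataclass(frozen=True)
class FilterPolicy:
    """Eligibility thresholds for small providers.

    ``min_n`` drops providers with fewer than ``min_n`` patients.  The default
    of 10 is the relaxed rule adequate for the adjustment estimators in this
    package; ``min_n=25`` reproduces the ad hoc convention common in the
    clinical literature.  ``min_median_n`` only triggers a warning when the
    median retained site size falls below it (identifiability of the provider
    density degrades when typical sites are very small).
    """

    min_n: int = 10
    min_median_n: int | None = 20

    def __post_init__(self):
        if self.min_n < 1:
            raise ValidationError("min_n must be >= 1")


def _infer_delimiter(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".tab") else ","


def read_counts(path) -> ProviderCounts:
    """Read a provider count table from delimited text.

    Two schemas are accepted:

    * provider-level: columns ``provider_id,y,n``, one row per provider;
    * patient-level: columns ``provider_id,outcome`` with outcome in {0, 1},
      one row per patient, aggregated by provider on ingestion.

    The delimiter is inferred from the extension (``.tsv`` -> tab, comma
    otherwise).
    """
    df = pd.read_csv(path, sep=_infer_delimiter(path))
    cols = set(df.columns)
    if {"provider_id", "y", "n"} <= cols:
        return ProviderCounts(
            df["provider_id"].to_numpy(dtype=object),
            df["y"].to_numpy(),
            df["n"].to_numpy(),
        )
    if {"provider_id", "outcome"} <= cols:
        out = df["outcome"]
        if not out.isin([0, 1]).all():
            raise ValidationError("patient-level outcome column must be 0/1")
        grouped = df.groupby("provider_id", sort=True)["outcome"].agg(["sum", "size"])
        return ProviderCounts(
            grouped.index.to_numpy(dtype=object),
            grouped["sum"].to_numpy(),
            grouped["size"].to_numpy(),
        )
    raise ValidationError(
        "missing columns: expected provider_id,y,n (provider-level) "
        "or provider_id,outcome (patient-level); got "
        + ", ".join(map(str, df.columns))
    )


def write_counts(counts: ProviderCounts, path) -> None:
    """Write the provider-level schema back out (round-trips ``read_counts``)."""
    counts.to_frame().to_csv(path, sep=_infer_delimiter(path), index=False)


def filter_small_sites(
    counts: ProviderCounts, policy: FilterPolicy = FilterPolicy()
) -> ProviderCounts:
    """Remove providers with fewer than ``policy.min_n`` patients.

    Logs the excluded fraction of providers and of patients (bookkeeping
    only), warns if the median retained site size is below
    ``policy.min_median_n``, and is idempotent for a fixed policy.
    """
    keep = counts.n >= policy.min_n
    if not keep.any():
        raise ValidationError(
            f"no providers remain after filtering at min_n={policy.min_n}"
        )
    dropped = ~keep
    frac_sites = dropped.mean()
    frac_patients = counts.n[dropped].sum() / counts.n.sum()
    logger.info(
        "small-site filter (min_n=%d): excluded %.1f%% of providers, %.2f%% of patients",
        policy.min_n,
        100 * frac_sites,
        100 * frac_patients,
    )
    out = ProviderCounts(counts.provider_id[keep], counts.y[keep], counts.n[keep])
    if policy.min_median_n is not None and np.median(out.n) < policy.min_median_n:
        warnings.warn(
            f"median retained site size {np.median(out.n):.0f} is below "
            f"{policy.min_median_n}; nonparametric recovery of the provider "
            "density may be unreliable",
            stacklevel=2,
        )
    return out
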