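"""Evaluation metrics and the Monte Carlo study driver.

Accuracy of an estimated provider-probability law is measured against the
scenario truth by

* bias and MSE of the variance estimate,
* the integrated squared distance between CDFs (ED-CDF) and densities
  (ED-PDF), computed by composite Simpson quadrature on a fixed 2001-point
  grid (a fixed grid is used deliberately: the step discontinuities of
  empirical CDFs defeat adaptive quadrature error estimates).

`run_study` repeats a scenario B times with counter-derived child seeds, so
every method sees the identical sequence of datasets (a paired design that
sharpens method comparisons), fits the requested methods, and aggregates the
metrics.  The variance-ratio column (mean estimate / true variance) is the
scale on which over- and under-dispersion are naturally compared across
scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .dp import dp_density, dp_fit, dp_preset
from .exceptions import ProviderVarError, ValidationError
from .ghm import eb_predictions, fit_ghm, ghm_density
from .mai import mai_estimate
from .raw import DistributionEstimate, raw_estimate
from .sbr import sbr_estimate, sbr_fit
from .simulate import (ScenarioSpec, gen_cluster_sizes, gen_outcomes,
                       gen_provider_probs, true_cdf, true_density, true_variance)

__all__ = ["MetricsReport", "ed_cdf", "ed_pdf", "bias_mse", "run_study",
           "plot_density_overlay", "METHODS"]

_ED_GRID_SIZE = 2001


def _squared_distance(f_est, f_true, lo: float, hi: float) -> float:
    t = np.linspace(lo, hi, _ED_GRID_SIZE)
    return float(simpson((f_est(t) - f_true(t)) ** 2, x=t))


def ed_cdf(estimate: DistributionEstimate, truth: ScenarioSpec) -> float:
    """Integrated squared CDF error on [0, 1].

    ``truth`` is a scenario (its exact CDF is used) or any CDF callable.
    """
    f_true = (lambda t: true_cdf(truth, t)) if isinstance(truth, ScenarioSpec) else truth
    return _squared_distance(estimate.cdf, f_true, 0.0, 1.0)


def ed_pdf(estimate: DistributionEstimate, truth: ScenarioSpec) -> float:
    """Integrated squared density error.

    The integration range extends past [0, 1] when the estimate's grid
    spills over (kernel tails); the true density is 0 there, so spill-over
    mass is penalised rather than ignored.  ``truth`` is a scenario or any
    density callable.
    """
    lo = min(0.0, float(estimate.grid[0]))
    hi = max(1.0, float(estimate.grid[-1]))
    f_true = (lambda t: true_density(truth, t)) if isinstance(truth, ScenarioSpec) else truth
    return _squared_distance(estimate.pdf_at, f_true, lo, hi)


def bias_mse(estimates, truth: float) -> tuple[float, float]:
    """Monte Carlo bias (mean - truth) and MSE (mean squared deviation)."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValidationError("bias_mse needs at least two replicates")
    bias = float(estimates.mean() - truth)
    mse = float(np.mean((estimates - truth) ** 2))
    return bias, mse


# ---------------------------------------------------------------------------
# method registry


def _fit_raw(counts, rng):
    return {"raw": raw_estimate(counts)}


def _fit_ghm_family(counts, rng, want_eb):
    fit = fit_ghm(counts)
    out = {"ghm": ghm_density(fit)}
    if want_eb:
        out["ghm_eb"] = eb_predictions(fit, counts)
    return out


def _fit_mai(counts, rng):
    return {"mai": mai_estimate(counts)}


def _fit_sbr(counts, rng):
    return {"sbr": sbr_estimate(sbr_fit(counts))}


def _fit_dp(counts, rng, preset, mcmc: dict):
    cfg = dp_preset(preset, seed=int(rng.integers(2**31 - 1)), **mcmc)
    res = dp_fit(counts, cfg)
    return {preset: dp_density(res, counts)}


METHODS = ("raw", "ghm", "ghm_eb", "mai", "sbr", "dp1", "dp2", "dp3")


@dataclass
class MetricsReport:
    """Aggregated study results.

    ``table`` is indexed by method with columns mean_variance, bias,
    variance_ratio, mse, mean_ed_cdf, mean_ed_pdf, pct_mse_reduction_vs_raw,
    pct_ed_cdf_reduction_vs_raw, n_ok, n_failed, valid.
    """

    spec: ScenarioSpec
    true_variance: float
    B: int
    base_seed: int
    table: pd.DataFrame
    per_replicate: pd.DataFrame = field(repr=False, default=None)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for method, row in self.table.iterrows():
            for metric, value in row.items():
                rows.append({
                    "law": self.spec.law, "sigma_b2": self.spec.sigma_b2,
                    "N": self.spec.N, "size_profile": str(self.spec.size_profile),
                    "method": method, "metric": metric, "value": value,
                })
        return pd.DataFrame(rows)


def run_study(spec: ScenarioSpec, methods=("raw", "ghm", "mai"), B: int = 200,
              base_seed: int = 0, dp_mcmc: dict | None = None,
              compute_ed: bool = True) -> MetricsReport:
    """Run every requested method on B paired replicates of a scenario.

    Child seeds are counter-based (``default_rng([base_seed, b])``) so
    reruns with the same base seed reproduce the report bit-for-bit, and all
    methods share identical datasets.  A method failing on a replicate is
    recorded and excluded from its aggregates; failing on more than 10% of
    replicates marks the whole column invalid.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")
    if B < 2:
        raise ValidationError("B must be >= 2")
    dp_mcmc = dp_mcmc or {}
    sigma_p2 = true_variance(spec)
    records = []
    for b in range(B):
        rng = np.random.default_rng([int(base_seed), b])
        p = gen_provider_probs(spec, rng=rng)
        n = gen_cluster_sizes(spec, rng=rng)
        counts = gen_outcomes(p, n, rng=rng)
        fits: dict[str, DistributionEstimate] = {}
        errors: dict[str, str] = {}

        def _try(names, fn):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits.update(fn())
            except ProviderVarError as exc:
                for name in names:
                    errors[name] = str(exc)

        if "raw" in methods:
            _try(["raw"], lambda: _fit_raw(counts, rng))
        if "ghm" in methods or "ghm_eb" in methods:
            want_eb = "ghm_eb" in methods
            _try(["ghm", "ghm_eb"],
                 lambda: _fit_ghm_family(counts, rng, want_eb))
        if "mai" in methods:
            _try(["mai"], lambda: _fit_mai(counts, rng))
        if "sbr" in methods:
            _try(["sbr"], lambda: _fit_sbr(counts, rng))
        for preset in ("dp1", "dp2", "dp3"):
            if preset in methods:
                _try([preset], lambda preset=preset: _fit_dp(counts, rng, preset, dp_mcmc))

        for method in methods:
            if method in fits:
                est = fits[method]
                rec = {"replicate": b, "method": method, "ok": True,
                       "variance": est.variance}
                if compute_ed:
                    rec["ed_cdf"] = ed_cdf(est, spec)
                    rec["ed_pdf"] = ed_pdf(est, spec)
                records.append(rec)
            else:
                records.append({"replicate": b, "method": method, "ok": False,
                                "error": errors.get(method, "not fitted")})

    per_rep = pd.DataFrame(records)
    rows = {}
    for method in methods:
        sub = per_rep[per_rep["method"] == method]
        ok = sub[sub["ok"]]
        n_ok, n_fail = len(ok), int((~sub["ok"]).sum())
        row = {"n_ok": n_ok, "n_failed": n_fail,
               "valid": n_fail <= 0.10 * B and n_ok >= 2}
        if n_ok >= 2:
            bias, mse = bias_mse(ok["variance"].to_numpy(), sigma_p2)
            row.update(
                mean_variance=ok["variance"].mean(), bias=bias, mse=mse,
                variance_ratio=ok["variance"].mean() / sigma_p2,
            )
            if compute_ed:
                row.update(mean_ed_cdf=ok["ed_cdf"].mean(),
                           mean_ed_pdf=ok["ed_pdf"].mean())
        rows[method] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if "raw" in table.index and "mse" in table.columns:
        raw_row = table.loc["raw"]
        table["pct_mse_reduction_vs_raw"] = 100 * (1 - table["mse"] / raw_row["mse"])
        if compute_ed:
            table["pct_ed_cdf_reduction_vs_raw"] = 100 * (
                1 - table["mean_ed_cdf"] / raw_row["mean_ed_cdf"]
            )
    return MetricsReport(spec=spec, true_variance=sigma_p2, B=B,
                         base_seed=base_seed, table=table, per_replicate=per_rep)


def plot_density_overlay(estimates, spec: ScenarioSpec | None = None, ax=None):
    """Overlay estimated densities (and optionally the scenario truth)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if spec is not None:
        g = np.linspace(1e-4, 1 - 1e-4, 512)
        ax.plot(g, true_density(spec, g), "k-", lw=2, label="truth")
    for est in estimates:
        ax.plot(est.grid, est.pdf, label=est.method)
    ax.set_xlabel("provider probability")
    ax.set_ylabel("density")
    ax.legend()
    return ax
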