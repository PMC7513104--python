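"""Benchmark-sensitivity analyses.

Two tools: a sweep that recomputes every divergence under a list of
candidate benchmark priors (each benchmark induces its own reference
posterior, so the whole pipeline reruns per column), and a grid
simulation mapping DAC values over a lattice of normal expert priors
N(mu0, sigma0^2) against one seeded dataset — the standard way to
visualize how the choice of benchmark moves the agreement region.

For uninformative benchmarks the reference posterior, and hence the
expert divergences and the ranking, barely move; only the denominator
KL (the disagreement threshold) shifts.  Informative benchmarks drag
the reference posterior with them and can change the verdicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .densities import DensitySpec, ExpertBelief
from .divergence import kl_divergence
from .errors import DegeneratePosteriorError, ValidationError
from .evidence import log_marginal_likelihood
from .posterior import ModelSpec, ObservationSet, fit_posterior
from .ranking import rank_experts

__all__ = ["SweepResult", "GridResult", "benchmark_sweep", "dac_grid_simulation", "benchmark_label"]


def benchmark_label(spec: DensitySpec) -> str:
    p = spec.params
    if spec.family == "normal":
        return f"normal({p['mean']:g}, sd={p['sd']:g})"
    if spec.family == "uniform":
        return f"uniform({p['lower']:g}, {p['upper']:g})"
    if spec.family == "skew_normal":
        return f"skew_normal({p['mu0']:g}, {p['sigma0']:g}, {p['gamma0']:g})"
    return "grid"


@dataclass
class SweepResult:
    """One column per benchmark: expert KLs, the benchmark KL, log evidence."""

    table: pd.DataFrame          # rows: kl[expert...], kl_J, log_m_J
    dac: pd.DataFrame            # rows: dac per expert, derived as kl_d / kl_J
    rankings: pd.DataFrame       # rows: dac_rank per expert
    failed: List[str]            # benchmark labels whose posterior degenerated


def benchmark_sweep(
    data: ObservationSet,
    experts: Sequence[ExpertBelief],
    benchmarks: Sequence[DensitySpec],
    model: ModelSpec,
) -> SweepResult:
    """Recompute KLs, DACs and evidence under each candidate benchmark."""
    if len(benchmarks) < 1:
        raise ValidationError("benchmark_sweep needs at least one benchmark")
    ids = [e.expert_id for e in experts]
    kl_rows = {f"kl[{i}]": [] for i in ids}
    kl_J_row, log_m_J_row = [], []
    dac_cols, rank_cols, labels, failed = {}, {}, [], []

    for bench in benchmarks:
        label = benchmark_label(bench)
        labels.append(label)
        try:
            post = fit_posterior(data, bench, model)
            kl_d = np.array([
                kl_divergence(post.density, e.density).value for e in experts
            ])
            kl_J = kl_divergence(post.density, bench).value
            log_m_J = log_marginal_likelihood(data, bench, model).log_m
        except DegeneratePosteriorError:
            failed.append(label)
            for i in ids:
                kl_rows[f"kl[{i}]"].append(math.nan)
            kl_J_row.append(math.nan)
            log_m_J_row.append(math.nan)
            dac_cols[label] = [math.nan] * len(ids)
            rank_cols[label] = [0] * len(ids)
            continue
        for i, v in zip(ids, kl_d):
            kl_rows[f"kl[{i}]"].append(v)
        kl_J_row.append(kl_J)
        log_m_J_row.append(log_m_J)
        dac = kl_d / kl_J
        dac_cols[label] = dac
        rank_cols[label] = rank_experts(dac, "ascending")

    rows = dict(kl_rows)
    rows["kl_J"] = kl_J_row
    rows["log_m_J"] = log_m_J_row
    table = pd.DataFrame(rows, index=labels).T
    return SweepResult(
        table=table,
        dac=pd.DataFrame(dac_cols, index=ids),
        rankings=pd.DataFrame(rank_cols, index=ids),
        failed=failed,
    )


@dataclass
class GridResult:
    """DAC over a lattice of normal expert priors, one benchmark, one dataset."""

    mu0: np.ndarray
    sigma0: np.ndarray
    dac: np.ndarray              # shape (len(sigma0), len(mu0))
    kl_J: float
    benchmark: str
    seed: int
    data_mean: float

    def to_long(self) -> pd.DataFrame:
        mu, sg = np.meshgrid(self.mu0, self.sigma0)
        return pd.DataFrame({
            "mu0": mu.ravel(), "sigma0": sg.ravel(), "dac": self.dac.ravel()
        })

    def dac_at(self, mu0: float, sigma0: float) -> float:
        """DAC for one off-grid prior N(mu0, sigma0^2), same data and benchmark."""
        return float(
            _kl_post_vs_normal(self._post_moments, np.array([mu0]), np.array([sigma0]))[0, 0]
            / self.kl_J
        )


def dac_grid_simulation(
    n: int = 100,
    seed: int = 1,
    mu_range: Sequence[float] | None = None,
    sigma_range: Sequence[float] | None = None,
    benchmark: DensitySpec | None = None,
    model: ModelSpec | None = None,
    data_mu: float = 0.0,
    data_sigma: float = 1.0,
) -> GridResult:
    """DAC surface over expert priors N(mu0, sigma0^2).

    One dataset of ``n`` draws from N(data_mu, data_sigma^2) is
    generated from ``seed`` and shared by every cell.  Defaults follow
    the usual design: n = 100 standard-normal draws, mu0 spanning the
    sample mean +/- 4 in steps of 0.1, sigma0 from 0.1 to 3 in steps of
    0.1.  Because each cell's prior is normal, the divergence from the
    fitted reference posterior reduces to its grid moments, so the
    whole surface is a closed-form array computation after one
    posterior fit.
    """
    from .fixtures import generate_dataset
    from .densities import normal as normal_spec

    if benchmark is None:
        benchmark = normal_spec(0.0, 100.0)
    if model is None:
        model = ModelSpec()
    data = generate_dataset(n=n, mu=data_mu, sigma=data_sigma, seed=seed)
    ybar = data.mean
    mu0 = np.asarray(
        mu_range if mu_range is not None else np.arange(ybar - 4.0, ybar + 4.0 + 1e-9, 0.1)
    )
    sigma0 = np.asarray(
        sigma_range if sigma_range is not None else np.arange(0.1, 3.0 + 1e-9, 0.1)
    )
    if mu0.size < 1 or sigma0.size < 1 or np.any(sigma0 <= 0):
        raise ValidationError("grid axes must be non-empty with positive sigma0")

    post = fit_posterior(data, benchmark, model)
    kl_J = kl_divergence(post.density, benchmark).value
    moments = _posterior_grid_moments(post.density)
    dac = _kl_post_vs_normal(moments, mu0, sigma0) / kl_J

    result = GridResult(
        mu0=mu0, sigma0=sigma0, dac=dac, kl_J=kl_J,
        benchmark=benchmark_label(benchmark), seed=seed, data_mean=ybar,
    )
    result._post_moments = moments
    return result


def _posterior_grid_moments(density: DensitySpec):
    """(neg_entropy, mean, variance) of the reference posterior."""
    if density.family == "normal":
        m, s = density.params["mean"], density.params["sd"]
        neg_entropy = -0.5 * math.log(2.0 * math.pi * math.e * s**2)
        return neg_entropy, m, s**2
    gx, gpdf = density.params["x"], density.params["pdf"]
    mask = gpdf > 0
    logp = np.log(np.where(mask, gpdf, 1.0))
    neg_entropy = float(np.trapezoid(np.where(mask, gpdf * logp, 0.0), gx))
    mean = float(np.trapezoid(gx * gpdf, gx))
    var = float(np.trapezoid((gx - mean) ** 2 * gpdf, gx))
    return neg_entropy, mean, var


def _kl_post_vs_normal(moments, mu0: np.ndarray, sigma0: np.ndarray) -> np.ndarray:
    """KL(posterior || N(mu0, sigma0^2)) for all grid cells at once.

    With q normal, integral p log q only needs E_p[(theta - mu0)^2], so
    KL = integral p log p + log(sigma0 sqrt(2 pi))
         + (var_p + (mean_p - mu0)^2) / (2 sigma0^2).
    """
    neg_entropy, mean_p, var_p = moments
    sg = sigma0[:, None]
    offset2 = (mean_p - mu0[None, :]) ** 2
    return (
        neg_entropy
        + np.log(sg * math.sqrt(2.0 * math.pi))
        + (var_p + offset2) / (2.0 * sg**2)
    )
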