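"""Marginal likelihoods and Bayes factors.

The marginal likelihood (evidence) m(y) = integral over Theta of
f(y | theta) pi(theta) dtheta is the probability of the data averaged
over a prior.  With the model and data held fixed across experts, the
evidence under each elicited prior measures how much probability that
expert gave to what was actually observed, and the Bayes factor
BF_ab = m_a(y) / m_b(y) gives the odds favouring prior a over prior b.

Everything is computed in log space: the empirical magnitudes in this
setting (~1e-68 for n around 100) are representable as doubles but their
products and ratios are not reliably so.  Conjugate closed forms are
used for normal and uniform priors on an unbounded parameter space;
every other case goes through a log-sum-exp trapezoid over the same
dense grid the posterior module uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .densities import DensitySpec, log_density_at
from .posterior import ModelSpec, ObservationSet, _posterior_grid
from .errors import DegeneratePosteriorError

__all__ = ["EvidenceResult", "log_marginal_likelihood", "bayes_factor"]


@dataclass(frozen=True)
class EvidenceResult:
    """Natural-log evidence for one prior; -inf when the prior excludes the data."""

    log_m: float
    prior_id: str = ""

    def __float__(self) -> float:
        return self.log_m


def log_marginal_likelihood(
    data: ObservationSet, prior: DensitySpec, model: ModelSpec, prior_id: str = ""
) -> EvidenceResult:
    """log m(y) = log integral of f(y | theta) pi(theta) dtheta.

    Writing the normal likelihood through its sufficient statistics,

        log f(y | theta) = -(n/2) log(2 pi sigma^2) - SS / (2 sigma^2)
                           - n (theta - ybar)^2 / (2 sigma^2),

    with SS the centred sum of squares, the theta integral reduces to
    averaging a N(ybar, sigma^2/n) kernel over the prior — closed form
    for normal and uniform priors, log-space quadrature otherwise.
    """
    sigma = model.resolve_sigma(data)
    n, ybar = data.n, data.mean
    ss = (n - 1) * data.sd**2 if n >= 2 else 0.0
    base = -0.5 * n * math.log(2.0 * math.pi * sigma**2) - ss / (2.0 * sigma**2)
    se = sigma / math.sqrt(n)
    kernel = 0.5 * math.log(2.0 * math.pi * se**2)  # log of the kernel's own normalizer

    unbounded = model.theta_bounds == (-math.inf, math.inf)
    if prior.family == "normal" and unbounded:
        mu0, tau = prior.params["mean"], prior.params["sd"]
        log_avg = stats.norm.logpdf(ybar, loc=mu0, scale=math.sqrt(se**2 + tau**2))
    elif prior.family == "uniform" and unbounded:
        lo, up = prior.params["lower"], prior.params["upper"]
        zmass = stats.norm.cdf(up, ybar, se) - stats.norm.cdf(lo, ybar, se)
        if zmass <= 0.0:
            return EvidenceResult(log_m=-math.inf, prior_id=prior_id)
        log_avg = math.log(zmass) - math.log(up - lo)
    else:
        try:
            theta = _posterior_grid(data, prior, model, sigma)
        except DegeneratePosteriorError:
            return EvidenceResult(log_m=-math.inf, prior_id=prior_id)
        logg = stats.norm.logpdf(theta, loc=ybar, scale=se) + np.asarray(
            log_density_at(prior, theta)
        )
        log_avg = _log_trapezoid(logg, theta)
        if not np.isfinite(log_avg):
            return EvidenceResult(log_m=-math.inf, prior_id=prior_id)

    return EvidenceResult(log_m=base + kernel + log_avg, prior_id=prior_id)


def bayes_factor(log_m_a: float, log_m_b: float) -> float:
    """exp(log_m_a - log_m_b); -inf sentinels propagate to 0 or +inf."""
    if log_m_a == -math.inf and log_m_b == -math.inf:
        return math.nan
    return float(np.exp(log_m_a - log_m_b))


def _log_trapezoid(logg: np.ndarray, x: np.ndarray) -> float:
    """log of the trapezoid integral of exp(logg), without leaving log space."""
    dx = np.diff(x)
    logw = np.concatenate((
        [np.log(dx[0] / 2.0)],
        np.log((dx[1:] + dx[:-1]) / 2.0),
        [np.log(dx[-1] / 2.0)],
    ))
    return float(logsumexp(logg + logw))
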