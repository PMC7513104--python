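"""Expert ranking by the Data Agreement Criterion and Bayes factors.

For experts d = 1..D with elicited priors pi_d(theta), a benchmark
prior pi_J(theta) and its reference posterior pi_J(theta | y):

- KL_d  = KL[pi_J(.|y) || pi_d]       loss of information of expert d
- DAC_d = KL_d / KL[pi_J(.|y) || pi_J]  the Data Agreement Criterion;
  DAC_d > 1 means expert d conflicts with the data more than the
  (uninformative) benchmark does — prior-data disagreement
- BF_Jd = m_J(y) / m_d(y)             odds favouring the benchmark;
  BF_Jd > 1 likewise signals disagreement
- DAC2_dJ = BF_Jd * exp(KL[pi_J(.|y) || pi_d(.|y)])  an alternative
  criterion whose extra posterior-divergence factor penalizes
  overconfident experts more harshly than the Bayes factor does

Experts are ranked ascending on DAC (equivalently on KL, since the
denominator is shared) and descending on evidence.  When no benchmark
is configured, raw KL divergences still rank the experts; only the
agreement/disagreement verdicts need the benchmark as a yardstick.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .densities import DensitySpec, ExpertBelief
from .divergence import kl_divergence
from .errors import ValidationError
from .evidence import bayes_factor, log_marginal_likelihood
from .posterior import ModelSpec, ObservationSet, PosteriorSummary, fit_posterior

__all__ = [
    "RankingConfig",
    "RankingReport",
    "dac_scores",
    "dac_vector",
    "full_report",
    "classify_agreement",
    "rank_experts",
    "pairwise_table",
    "PairwiseTable",
    "dac2",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankingConfig:
    """Everything a ranking run needs: experts, benchmark, model, data."""

    experts: List[ExpertBelief]
    benchmark: Optional[DensitySpec]
    model: ModelSpec
    data: ObservationSet

    def __post_init__(self):
        if len(self.experts) < 1:
            raise ValidationError("at least one expert is required")


@dataclass
class RankingReport:
    """Per-expert scores plus the benchmark row quantities."""

    expert_ids: List[str]
    kl: np.ndarray                       # KL[pi_J(.|y) || pi_d]
    kl_J: Optional[float] = None         # KL[pi_J(.|y) || pi_J]
    dac: Optional[np.ndarray] = None
    dac_rank: Optional[np.ndarray] = None
    agreement_dac: Optional[List[str]] = None
    log_m: Optional[np.ndarray] = None
    log_m_J: Optional[float] = None
    bf_Jd: Optional[np.ndarray] = None
    bf_rank: Optional[np.ndarray] = None
    agreement_bf: Optional[List[str]] = None
    dac2: Optional[np.ndarray] = None
    reference_posterior: Optional[PosteriorSummary] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        cols = {"expert_id": self.expert_ids, "kl": self.kl}
        for name in ("dac", "dac_rank", "log_m", "bf_Jd", "bf_rank", "dac2",
                     "agreement_dac", "agreement_bf"):
            val = getattr(self, name)
            if val is not None:
                cols[name] = val
        return pd.DataFrame(cols)


def classify_agreement(score: float) -> str:
    """"disagreement" iff the criterion strictly exceeds 1 (DAC or BF_Jd)."""
    if score < 0:
        raise ValidationError(f"criterion scores are non-negative, got {score}")
    return "disagreement" if score > 1.0 else "agreement"


def rank_experts(scores: Sequence[float], direction: str = "ascending") -> np.ndarray:
    """Ranks 1..D, rank 1 best; ties broken by input order with a warning."""
    arr = np.asarray(scores, dtype=float)
    if direction not in ("ascending", "descending"):
        raise ValidationError(f"direction must be ascending or descending, got {direction!r}")
    key = arr if direction == "ascending" else -arr
    if len(np.unique(arr)) < arr.size:
        logger.warning("tied scores: ranks broken by expert input order")
    order = np.argsort(key, kind="stable")
    ranks = np.empty(arr.size, dtype=int)
    ranks[order] = np.arange(1, arr.size + 1)
    return ranks


def dac_scores(
    reference_posterior: DensitySpec,
    priors: Sequence[DensitySpec],
    benchmark: DensitySpec,
):
    """(kl_d, kl_J, dac_d) against a given reference posterior density.

    This is the core ratio of divergences; `dac_vector` wraps it with
    the posterior fit.  Raises when the benchmark coincides with the
    reference posterior (zero denominator makes the ratio meaningless).
    """
    kl_d = np.array([kl_divergence(reference_posterior, q).value for q in priors])
    kl_J = kl_divergence(reference_posterior, benchmark).value
    if not (kl_J > 0.0):
        raise ValidationError(
            "benchmark equals the reference posterior (KL = 0): DAC is undefined"
        )
    return kl_d, kl_J, kl_d / kl_J


def dac_vector(config: RankingConfig) -> RankingReport:
    """KL and DAC fields of the report: one posterior fit, D + 1 divergences."""
    if config.benchmark is None:
        return _benchmark_free_report(config)
    post = fit_posterior(config.data, config.benchmark, config.model)
    kl_d, kl_J, dac = dac_scores(
        post.density, [e.density for e in config.experts], config.benchmark
    )
    return RankingReport(
        expert_ids=[e.expert_id for e in config.experts],
        kl=kl_d,
        kl_J=kl_J,
        dac=dac,
        dac_rank=rank_experts(dac, "ascending"),
        agreement_dac=[classify_agreement(v) for v in dac],
        reference_posterior=post,
    )


def full_report(config: RankingConfig) -> RankingReport:
    """Complete report: DAC, evidence, Bayes factors, DAC2, both rankings."""
    report = dac_vector(config)
    log_m = np.array([
        log_marginal_likelihood(config.data, e.density, config.model, e.expert_id).log_m
        for e in config.experts
    ])
    report.log_m = log_m
    if config.benchmark is None:
        return report
    report.log_m_J = log_marginal_likelihood(
        config.data, config.benchmark, config.model, "benchmark"
    ).log_m
    report.bf_Jd = np.array([bayes_factor(report.log_m_J, lm) for lm in log_m])
    report.bf_rank = rank_experts(log_m, "descending")
    report.agreement_bf = [classify_agreement(v) for v in report.bf_Jd]

    ref = report.reference_posterior.density
    dac2_vals = []
    for e, log_bf in zip(config.experts, np.log(report.bf_Jd)):
        expert_post = fit_posterior(config.data, e.density, config.model)
        kl_posts = kl_divergence(ref, expert_post.density).value
        dac2_vals.append(dac2(log_bf, kl_posts))
    report.dac2 = np.array(dac2_vals)
    return report


def dac2(log_bf_Jd: float, kl_posteriors: float) -> float:
    """DAC2_dJ = BF_Jd * exp(KL between the reference and expert posteriors)."""
    if kl_posteriors < 0:
        raise ValidationError("posterior KL must be non-negative")
    return float(np.exp(log_bf_Jd + kl_posteriors))


@dataclass(frozen=True)
class PairwiseTable:
    """D x D expert-vs-expert comparison: row over column."""

    kl_ratio: pd.DataFrame  # loss of information of row relative to column
    bf: pd.DataFrame        # odds in favour of row over column


def pairwise_table(
    kl: Sequence[float], log_m: Sequence[float], expert_ids: Sequence[str] | None = None
) -> PairwiseTable:
    """Benchmark-free comparison: KL ratios and Bayes factors between experts."""
    kl = np.asarray(kl, dtype=float)
    log_m = np.asarray(log_m, dtype=float)
    if np.any(kl <= 0):
        raise ValidationError("pairwise KL ratios need strictly positive KL values")
    if np.any(~np.isfinite(log_m)):
        raise ValidationError("pairwise Bayes factors need finite log marginals")
    ids = list(expert_ids) if expert_ids is not None else [
        f"expert_{i + 1}" for i in range(kl.size)
    ]
    ratio = kl[:, None] / kl[None, :]
    bf = np.exp(log_m[:, None] - log_m[None, :])
    np.fill_diagonal(ratio, 1.0)
    np.fill_diagonal(bf, 1.0)
    return PairwiseTable(
        kl_ratio=pd.DataFrame(ratio, index=ids, columns=ids),
        bf=pd.DataFrame(bf, index=ids, columns=ids),
    )


def _benchmark_free_report(config: RankingConfig) -> RankingReport:
    # recommendation for arbitrary-benchmark settings: rank on raw KL only
    model = config.model
    prior_union = _envelope_prior(config)
    post = fit_posterior(config.data, prior_union, model)
    kl_d = np.array([
        kl_divergence(post.density, e.density).value for e in config.experts
    ])
    return RankingReport(
        expert_ids=[e.expert_id for e in config.experts],
        kl=kl_d,
        dac_rank=rank_experts(kl_d, "ascending"),
        reference_posterior=post,
    )


def _envelope_prior(config: RankingConfig) -> DensitySpec:
    """A wide flat prior so the reference posterior is data-dominated."""
    from .densities import uniform

    sd = config.data.sd if config.data.sd is not None else config.model.resolve_sigma(config.data)
    half = 50.0 * sd
    return uniform(config.data.mean - half, config.data.mean + half)
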