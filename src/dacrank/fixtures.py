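"""Synthetic data generation and packaged reference fixtures.

The packaged CSVs carry the published turnover-elicitation study
numbers used by the regression tests: the four elicited skew-normal
priors (location / scale / shape as reported), the per-expert score
table (KL divergences, DAC scores, marginal likelihoods, Bayes factors
and both rankings) and the pairwise expert-vs-expert table.  Those
tables are *printed at two decimals / three significant digits*, so
arithmetic recomputed from them is rounding-limited; see
docs/methods.md for the tolerance tiers the tests use.

The synthetic generators emulate the study's data shape (one
positive-valued outcome per professional, approximately normal) and
the panel structure (experts differing in location and confidence);
they do not emulate elicitation noise or expert correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List

import numpy as np
import pandas as pd

from .densities import DensitySpec, ExpertBelief, normal
from .errors import ValidationError
from .posterior import ObservationSet

__all__ = [
    "worked_example",
    "table1_experts",
    "table2_printed",
    "table4_printed",
    "generate_dataset",
    "synthetic_expert_panel",
]


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("dacrank.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def worked_example() -> Dict[str, DensitySpec]:
    """The textbook DAC illustration: N(0,1) reference posterior,
    N(0.5, 1) expert prior, N(0, 900) benchmark (variance 900, SD 30)."""
    return {
        "reference_posterior": normal(0.0, 1.0),
        "expert_prior": normal(0.5, 1.0),
        "benchmark": normal(0.0, 30.0),
    }


def table1_experts() -> List[ExpertBelief]:
    """The four elicited skew-normal expert priors."""
    df = _read_csv("table1_experts.csv")
    return [
        ExpertBelief(r.expert_id, r.mu0, r.sigma0, r.gamma0)
        for r in df.itertuples(index=False)
    ]


def table2_printed() -> pd.DataFrame:
    """Published per-expert scores (printed precision), benchmark row last."""
    return _read_csv("table2_printed.csv").set_index("row_id")


def table4_printed() -> pd.DataFrame:
    """Published pairwise table, long format: (row, col) -> kl_ratio, bf."""
    return _read_csv("table4_printed.csv").set_index(["row", "col"])


def generate_dataset(n: int, mu: float, sigma: float, seed: int) -> ObservationSet:
    """Seeded i.i.d. normal observations with computed sufficient statistics."""
    if n < 2:
        raise ValidationError(f"generate_dataset needs n >= 2, got {n}")
    if not (sigma > 0):
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    rng = np.random.default_rng(seed)
    return ObservationSet.from_values(rng.normal(mu, sigma, size=n))


#: fixed (offset from truth, scale, shape) roles for the first panel members:
#: near-truth, biased, overconfident -- the canonical elicitation archetypes
_PANEL_ROLES = [
    (0.0, 0.30, 1.00),   # near-truth, honest uncertainty
    (1.20, 0.45, 1.10),  # biased location
    (0.60, 0.05, 0.90),  # overconfident: decent location, far too narrow
]


def synthetic_expert_panel(k: int, truth_mu: float, seed: int) -> List[ExpertBelief]:
    """A panel of ``k`` skew-normal beliefs around ``truth_mu``.

    The first three members (when present) take the near-truth, biased
    and overconfident roles above, so their divergence ordering against
    a data-dominated posterior at ``truth_mu`` is known a priori; any
    further members get seeded offsets and heterogeneous scales.
    """
    if k < 1:
        raise ValidationError(f"panel size must be >= 1, got {k}")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(k):
        if i < len(_PANEL_ROLES):
            off, scale, shape = _PANEL_ROLES[i]
        else:
            off = float(rng.normal(0.0, 1.0))
            scale = float(rng.uniform(0.1, 0.8))
            shape = float(rng.uniform(0.7, 1.3))
        panel.append(
            ExpertBelief(f"expert_{i + 1}", truth_mu + off, scale, shape)
        )
    return panel
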