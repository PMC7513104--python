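"""One-dimensional probability densities used throughout the package.

Four families cover every density the method needs: ``normal`` and
``uniform`` for benchmarks and textbook examples, the two-piece
(Fernandez-Steel) ``skew_normal`` for elicited expert beliefs, and
``grid`` for numerically fitted posteriors.

The two-piece skew normal takes a symmetric base density (here the
normal) and rescales its two halves by a shape parameter ``gamma0``:
with ``eps = (x - mu0) / sigma0``,

    pdf(x) = (1/sigma0) * 2/(gamma0 + 1/gamma0)
             * [ phi(eps / gamma0)   if eps >= 0
                 phi(gamma0 * eps)   otherwise ]

``gamma0 = 1`` recovers the symmetric normal; ``gamma0 > 1`` skews
right, ``gamma0 < 1`` skews left.  Note that ``mu0`` is the mode of the
base symmetric density (the centre of the transform), not the mean of
the resulting distribution, and ``sigma0`` is stored as a standard
deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "DensitySpec",
    "ExpertBelief",
    "normal",
    "uniform",
    "make_skew_normal",
    "grid_density",
    "density_at",
    "log_density_at",
    "support_of",
    "sample_from",
    "moments_of",
]

_FAMILIES = ("normal", "uniform", "skew_normal", "grid")


@dataclass(frozen=True)
class DensitySpec:
    """A validated one-dimensional probability density.

    Parameters are family specific:

    - ``normal``: ``mean``, ``sd`` (> 0)
    - ``uniform``: ``lower`` < ``upper``
    - ``skew_normal``: ``mu0`` (location = mode of the symmetric base),
      ``sigma0`` (scale, SD of the base, > 0), ``gamma0`` (shape, > 0)
    - ``grid``: strictly increasing abscissae ``x`` with non-negative
      ordinates ``pdf``; renormalized to trapezoid-integral 1 on
      construction
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown density family {self.family!r}")
        p = self.params
        if self.family == "normal":
            if not (p.get("sd", 0.0) > 0):
                raise ValidationError(f"normal sd must be > 0, got {p.get('sd')}")
        elif self.family == "uniform":
            if not (p.get("lower", math.inf) < p.get("upper", -math.inf)):
                raise ValidationError(
                    f"uniform requires lower < upper, got {p.get('lower')}, {p.get('upper')}"
                )
        elif self.family == "skew_normal":
            if not (p.get("sigma0", 0.0) > 0):
                raise ValidationError(f"skew_normal sigma0 must be > 0, got {p.get('sigma0')}")
            if not (p.get("gamma0", 0.0) > 0):
                raise ValidationError(f"skew_normal gamma0 must be > 0, got {p.get('gamma0')}")
        elif self.family == "grid":
            x = np.asarray(p["x"], dtype=float)
            pdf = np.asarray(p["pdf"], dtype=float)
            if x.ndim != 1 or x.shape != pdf.shape or x.size < 2:
                raise ValidationError("grid requires matching 1-D x and pdf arrays, length >= 2")
            if not np.all(np.diff(x) > 0):
                raise ValidationError("grid abscissae must be strictly increasing")
            if np.any(pdf < 0):
                raise ValidationError("grid ordinates must be non-negative")
            total = np.trapezoid(pdf, x)
            if not (total > 0) or not np.isfinite(total):
                raise ValidationError("grid density has zero or non-finite total mass")
            # renormalize on construction so downstream integrals are consistent
            object.__setattr__(self, "params", {"x": x, "pdf": pdf / total})

    # convenience -----------------------------------------------------------
    def pdf(self, x):
        return density_at(self, x)

    def logpdf(self, x):
        return log_density_at(self, x)

    @property
    def support(self) -> Tuple[float, float]:
        return support_of(self)


def normal(mean: float, sd: float) -> DensitySpec:
    """Normal density N(mean, sd^2); ``sd`` is a standard deviation."""
    return DensitySpec("normal", {"mean": float(mean), "sd": float(sd)})


def uniform(lower: float, upper: float) -> DensitySpec:
    return DensitySpec("uniform", {"lower": float(lower), "upper": float(upper)})


def make_skew_normal(mu0: float, sigma0: float, gamma0: float) -> DensitySpec:
    """Two-piece skew normal with location ``mu0``, scale ``sigma0``, shape ``gamma0``.

    The normalizing constant 2/(gamma0 + 1/gamma0) makes the density
    integrate to 1 exactly for every positive shape, so no numerical
    renormalization is needed.
    """
    return DensitySpec(
        "skew_normal",
        {"mu0": float(mu0), "sigma0": float(sigma0), "gamma0": float(gamma0)},
    )


def grid_density(x, pdf) -> DensitySpec:
    """Gridded density on strictly increasing abscissae; renormalized."""
    return DensitySpec("grid", {"x": x, "pdf": pdf})


@dataclass(frozen=True)
class ExpertBelief:
    """One expert's elicited prior: a skew-normal location/scale/shape triple.

    ``sigma0`` is a standard deviation (see module docstring for the
    scale-vs-variance ambiguity in elicitation practice).
    """

    expert_id: str
    mu0: float
    sigma0: float
    gamma0: float = 1.0

    def __post_init__(self):
        if not (self.sigma0 > 0):
            raise ValidationError(f"expert {self.expert_id!r}: sigma0 must be > 0, got {self.sigma0}")
        if not (self.gamma0 > 0):
            raise ValidationError(f"expert {self.expert_id!r}: gamma0 must be > 0, got {self.gamma0}")

    @property
    def density(self) -> DensitySpec:
        return make_skew_normal(self.mu0, self.sigma0, self.gamma0)


# ---------------------------------------------------------------------------
# evaluation


def density_at(spec: DensitySpec, x) -> np.ndarray | float:
    """Density value(s) at ``x``; exactly 0 outside the support."""
    x = np.asarray(x, dtype=float)
    p = spec.params
    if spec.family == "normal":
        out = stats.norm.pdf(x, loc=p["mean"], scale=p["sd"])
    elif spec.family == "uniform":
        lo, up = p["lower"], p["upper"]
        out = np.where((x >= lo) & (x <= up), 1.0 / (up - lo), 0.0)
    elif spec.family == "skew_normal":
        out = _two_piece_pdf(x, p["mu0"], p["sigma0"], p["gamma0"])
    else:  # grid
        gx, gpdf = p["x"], p["pdf"]
        out = np.interp(x, gx, gpdf, left=0.0, right=0.0)
    return out if out.ndim else float(out)


def log_density_at(spec: DensitySpec, x) -> np.ndarray | float:
    """Log density; -inf where the density is 0."""
    x = np.asarray(x, dtype=float)
    p = spec.params
    if spec.family == "normal":
        out = stats.norm.logpdf(x, loc=p["mean"], scale=p["sd"])
    elif spec.family == "uniform":
        lo, up = p["lower"], p["upper"]
        out = np.where((x >= lo) & (x <= up), -math.log(up - lo), -np.inf)
    elif spec.family == "skew_normal":
        mu0, s0, g0 = p["mu0"], p["sigma0"], p["gamma0"]
        eps = (x - mu0) / s0
        z = np.where(eps >= 0, eps / g0, eps * g0)
        out = (
            math.log(2.0 / (g0 + 1.0 / g0))
            - math.log(s0)
            + stats.norm.logpdf(z)
        )
    else:  # grid
        with np.errstate(divide="ignore"):
            out = np.log(density_at(spec, x))
    return out if out.ndim else float(out)


def _two_piece_pdf(x, mu0, sigma0, gamma0):
    eps = (x - mu0) / sigma0
    z = np.where(eps >= 0, eps / gamma0, eps * gamma0)
    c = 2.0 / (gamma0 + 1.0 / gamma0)
    return c / sigma0 * stats.norm.pdf(z)


def support_of(spec: DensitySpec) -> Tuple[float, float]:
    """Smallest closed interval outside which the density is 0."""
    p = spec.params
    if spec.family in ("normal", "skew_normal"):
        return (-math.inf, math.inf)
    if spec.family == "uniform":
        return (p["lower"], p["upper"])
    return (float(p["x"][0]), float(p["x"][-1]))


def moments_of(spec: DensitySpec) -> Tuple[float, float]:
    """(mean, sd) of the density; closed form where available, else grid moments."""
    p = spec.params
    if spec.family == "normal":
        return p["mean"], p["sd"]
    if spec.family == "uniform":
        lo, up = p["lower"], p["upper"]
        return 0.5 * (lo + up), (up - lo) / math.sqrt(12.0)
    if spec.family == "skew_normal":
        # absolute moments of the two-piece construction (base = normal)
        mu0, s0, g = p["mu0"], p["sigma0"], p["gamma0"]
        m1 = math.sqrt(2.0 / math.pi)  # E|Z| for standard normal
        mean_eps = m1 * (g - 1.0 / g)
        ex2 = g**2 - 1.0 + 1.0 / g**2  # E[eps^2] of the two-piece construction
        var_eps = ex2 - mean_eps**2
        return mu0 + s0 * mean_eps, s0 * math.sqrt(var_eps)
    gx, gpdf = p["x"], p["pdf"]
    mean = float(np.trapezoid(gx * gpdf, gx))
    var = float(np.trapezoid((gx - mean) ** 2 * gpdf, gx))
    return mean, math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# sampling


def sample_from(spec: DensitySpec, n: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. draws; identical (spec, n, seed) gives identical output."""
    if n < 1:
        raise ValidationError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    p = spec.params
    if spec.family == "normal":
        return rng.normal(p["mean"], p["sd"], size=n)
    if spec.family == "uniform":
        return rng.uniform(p["lower"], p["upper"], size=n)
    if spec.family == "skew_normal":
        # two-piece construction: the right half carries mass g^2/(1+g^2)
        mu0, s0, g = p["mu0"], p["sigma0"], p["gamma0"]
        right = rng.random(n) < g**2 / (1.0 + g**2)
        absz = np.abs(rng.standard_normal(n))
        return mu0 + s0 * np.where(right, absz * g, -absz / g)
    # grid: inverse CDF by linear interpolation of the cumulative trapezoid
    gx, gpdf = p["x"], p["pdf"]
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (gpdf[1:] + gpdf[:-1]) * np.diff(gx))))
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, gx)
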