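import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from dacrank import (
    DensitySpec,
    ExpertBelief,
    ValidationError,
    density_at,
    grid_density,
    log_density_at,
    make_skew_normal,
    normal,
    sample_from,
    support_of,
    uniform,
)
from dacrank.densities import moments_of


@pytest.mark.parametrize(
    "spec, x, expected",
    [
        (normal(0, 1), 0.0, 1.0 / math.sqrt(2 * math.pi)),
        (uniform(0, 5), 2.0, 0.2),
        (uniform(0, 5), 6.0, 0.0),
        (uniform(0, 5), -0.1, 0.0),
        # two-piece with shape 2 at its mode: (2 / (2 + 1/2)) * phi(0)
        (make_skew_normal(0, 1, 2), 0.0, 0.8 * stats.norm.pdf(0.0)),
    ],
)
def test_density_at_known_values(spec, x, expected):
    assert density_at(spec, x) == pytest.approx(expected, abs=1e-9)


def test_log_density_matches_density_and_is_neginf_outside_support():
    spec = uniform(0, 5)
    assert log_density_at(spec, 2.0) == pytest.approx(math.log(0.2))
    assert log_density_at(spec, 7.0) == -math.inf
    sn = make_skew_normal(1.0, 0.5, 1.7)
    xs = np.linspace(-3, 5, 41)
    np.testing.assert_allclose(np.exp(log_density_at(sn, xs)), density_at(sn, xs), rtol=1e-12)


def test_shape_one_recovers_the_normal_pdf():
    sn = make_skew_normal(0.3, 1.2, 1.0)
    xs = np.linspace(-5, 6, 100)
    np.testing.assert_allclose(
        density_at(sn, xs), stats.norm.pdf(xs, 0.3, 1.2), atol=1e-12, rtol=0
    )


def test_two_piece_density_is_continuous_at_the_mode():
    sn = make_skew_normal(2.0, 0.5, 0.8)
    eps = 1e-9
    left, right = density_at(sn, 2.0 - eps), density_at(sn, 2.0 + eps)
    assert abs(left - right) < 1e-8


@pytest.mark.parametrize(
    "spec",
    [
        normal(0, 1),
        normal(-3, 0.2),
        uniform(-2, 7),
        make_skew_normal(0, 1, 2),
        make_skew_normal(2.35, 0.11, 0.94),  # an elicited expert's parameters
        make_skew_normal(2.15, 0.09, 0.78),
    ],
    ids=lambda s: f"{s.family}:{sorted(s.params.values()) if s.family != 'grid' else 'grid'}",
)
def test_every_family_integrates_to_one(spec):
    mean, sd = moments_of(spec)
    lo, hi = support_of(spec)
    lo, hi = max(lo, mean - 14 * sd), min(hi, mean + 14 * sd)
    total, _ = integrate.quad(lambda x: density_at(spec, x), lo, hi, limit=200)
    assert total == pytest.approx(1.0, abs=1e-8)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    mu0=st.floats(-5, 5),
    sigma0=st.floats(0.05, 10),
    gamma0=st.floats(0.2, 5),
)
def test_skew_normal_normalization_and_skew_direction(mu0, sigma0, gamma0):
    sn = make_skew_normal(mu0, sigma0, gamma0)
    total, _ = integrate.quad(
        lambda x: density_at(sn, x),
        mu0 - 14 * sigma0 * max(1, 1 / gamma0),
        mu0 + 14 * sigma0 * max(1, gamma0),
        points=[mu0], limit=200,
    )
    assert total == pytest.approx(1.0, abs=1e-8)
    mean, _ = moments_of(sn)
    if gamma0 > 1:
        assert mean > mu0  # right skew
    elif gamma0 < 1:
        assert mean < mu0


def test_grid_density_renormalizes_on_construction():
    x = np.linspace(0, 1, 101)
    g = grid_density(x, np.full_like(x, 7.0))  # un-normalized flat ordinates
    assert np.trapezoid(g.params["pdf"], x) == pytest.approx(1.0, abs=1e-12)
    assert density_at(g, 0.5) == pytest.approx(1.0)
    assert density_at(g, 1.5) == 0.0


@pytest.mark.parametrize(
    "spec, expected",
    [
        (normal(0, 1), (-math.inf, math.inf)),
        (uniform(0, 5), (0.0, 5.0)),
        (make_skew_normal(2, 0.1, 0.8), (-math.inf, math.inf)),
    ],
)
def test_support_of(spec, expected):
    assert support_of(spec) == expected


@pytest.mark.parametrize(
    "bad",
    [
        lambda: normal(0, 0.0),
        lambda: normal(0, -1),
        lambda: uniform(5, 5),
        lambda: uniform(2, -2),
        lambda: make_skew_normal(0, -0.1, 1),
        lambda: make_skew_normal(0, 1, 0),
        lambda: grid_density([0, 1, 0.5], [1, 1, 1]),
        lambda: grid_density([0, 1], [-1, 1]),
        lambda: ExpertBelief("e", 0, -0.1, 1),
        lambda: ExpertBelief("e", 0, 1, -2),
    ],
)
def test_invalid_parameters_raise(bad):
    with pytest.raises(ValidationError):
        bad()


class TestSampling:
    @pytest.mark.parametrize(
        "spec",
        [normal(2, 1), uniform(0, 5), make_skew_normal(1, 0.5, 1.4)],
        ids=lambda s: s.family,
    )
    def test_same_seed_same_draws(self, spec):
        a = sample_from(spec, 500, seed=11)
        b = sample_from(spec, 500, seed=11)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, sample_from(spec, 500, seed=12))

    def test_normal_sample_mean(self):
        draws = sample_from(normal(2, 1), 100_000, seed=5)
        assert draws.mean() == pytest.approx(2.0, abs=0.02)  # 4 sigma / sqrt(n)

    def test_uniform_draws_stay_in_support(self):
        draws = sample_from(uniform(0, 5), 10_000, seed=3)
        assert draws.min() >= 0.0 and draws.max() <= 5.0

    def test_skew_normal_draws_match_closed_form_moments(self):
        sn = make_skew_normal(2.0, 0.5, 1.8)
        mean, sd = moments_of(sn)
        draws = sample_from(sn, 200_000, seed=9)
        assert draws.mean() == pytest.approx(mean, abs=4 * sd / math.sqrt(200_000))
        assert draws.std(ddof=1) == pytest.approx(sd, rel=0.02)

    def test_grid_sampling_by_inverse_cdf(self):
        x = np.linspace(-4, 4, 2001)
        g = grid_density(x, stats.norm.pdf(x))
        draws = sample_from(g, 100_000, seed=2)
        assert draws.mean() == pytest.approx(0.0, abs=0.02)
        assert draws.std(ddof=1) == pytest.approx(1.0, rel=0.02)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValidationError):
            sample_from(normal(0, 1), 0, seed=1)
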