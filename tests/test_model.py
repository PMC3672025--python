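"""Tests of the two-peak density and the censored Poisson region likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import norm

from nextpeak.model import (
    ConsistencyError,
    GlobalShape,
    RegionParams,
    RegionTags,
    density_left,
    density_right,
    intensity,
    region_log_likelihood,
)


def convolution_oracle(x, mu, sigma, beta):
    """Numeric quadrature of the normal x exponential convolution integral."""
    lo = min(x, mu) - 40 * sigma  # integrand mass is negligible below this
    val, _ = integrate.quad(
        lambda xi: (1.0 / beta)
        * math.exp(-(x - xi) / beta)
        * norm.pdf(xi, loc=mu, scale=sigma),
        lo,
        x,
        epsabs=1e-13,
        epsrel=1e-13,
        limit=200,
    )
    return val


@pytest.mark.parametrize("sigma,beta", [(10, 20), (40, 60), (80, 120)])
def test_density_normalizes_to_one(sigma, beta):
    shape = GlobalShape(sigma=sigma, beta=beta)
    mu = 0.0
    xs = np.arange(mu - 20 * sigma, mu + 20 * (sigma + beta), 0.1)
    assert abs(np.trapezoid(density_right(xs, mu, shape), xs) - 1.0) < 1e-6
    # the left density mirrors the right: its heavy tail points left
    xs_l = np.arange(mu - 20 * (sigma + beta), mu + 20 * sigma, 0.1)
    assert abs(np.trapezoid(density_left(xs_l, mu, shape), xs_l) - 1.0) < 1e-6


def test_density_matches_quadrature_oracle(shape):
    mu = 0.0
    rng = np.random.default_rng(11)
    xs = np.concatenate([[mu], rng.uniform(-300, 600, 49)])
    for x in xs:
        assert density_right(x, mu, shape) == pytest.approx(
            convolution_oracle(x, mu, shape.sigma, shape.beta), abs=1e-9
        )


def test_density_matches_scipy_exponnorm(shape):
    # independent library cross-check of the closed form
    from scipy.stats import exponnorm

    ref = exponnorm(K=shape.beta / shape.sigma, loc=100.0, scale=shape.sigma)
    xs = np.linspace(-500, 1000, 101)
    np.testing.assert_allclose(density_right(xs, 100.0, shape), ref.pdf(xs), atol=1e-12)


def test_mirror_identity(shape):
    mu = 123.0
    z = np.arange(-500, 501, dtype=float)
    np.testing.assert_allclose(
        density_left(mu - z, mu, shape), density_right(mu + z, mu, shape), atol=1e-12, rtol=0
    )


def test_left_tail_vanishes_fast(shape):
    mu = 0.0
    assert density_right(mu - 10 * shape.sigma, mu, shape) < 1e-12


def test_log_space_stability(shape):
    # the exp factor alone would overflow at offsets ~ -1e4 * beta
    x = -1e4 * shape.beta
    val = density_right(x, 0.0, shape)
    assert np.isfinite(val) and val >= 0.0


def test_density_rejects_non_finite(shape):
    with pytest.raises(ValueError):
        density_right(np.nan, 0.0, shape)
    with pytest.raises(ValueError):
        density_right(0.0, np.inf, shape)


def test_shape_and_params_invariants():
    with pytest.raises(ValueError):
        GlobalShape(sigma=-1, beta=60)
    with pytest.raises(ValueError):
        GlobalShape(sigma=40, beta=0)
    with pytest.raises(ValueError):
        RegionParams(mu=0, nu=-1, rho=0.1)


def test_intensity_reduces_to_background(shape):
    params = RegionParams(mu=50.0, nu=0.0, rho=0.3)
    j = np.arange(1, 101)
    for strand in ("left", "right"):
        np.testing.assert_array_equal(intensity(j, strand, params, shape), 0.3)


def test_intensity_total_excess_equals_nu(shape):
    # sum over a wide region of (lambda - rho) approximates nu
    mu = 0.0
    params = RegionParams(mu=mu, nu=137.0, rho=0.05)
    j = np.arange(mu - 20 * (shape.sigma + shape.beta), mu + 20 * (shape.sigma + shape.beta))
    excess = np.sum(intensity(j, "right", params, shape) - params.rho)
    assert excess == pytest.approx(params.nu, rel=1e-3)


def test_intensity_mirror(shape):
    params = RegionParams(mu=200.0, nu=80.0, rho=0.2)
    z = np.arange(-300, 301)
    np.testing.assert_allclose(
        intensity(200.0 - z, "left", params, shape),
        intensity(200.0 + z, "right", params, shape),
        rtol=1e-12,
    )


def test_loglik_all_unmappable_is_zero(shape):
    tags = RegionTags(
        start=1,
        counts_left=np.zeros(10, dtype=int),
        counts_right=np.zeros(10, dtype=int),
        unmappable_left=np.ones(10, dtype=bool),
        unmappable_right=np.ones(10, dtype=bool),
    )
    params = RegionParams(mu=5.0, nu=10.0, rho=0.5)
    assert region_log_likelihood(tags, params, shape) == 0.0


def test_loglik_matches_hand_computation(shape):
    # 5-bp region, hand-written counts; Poisson log-pmfs summed by hand
    counts_l = np.array([0, 1, 2, 0, 1])
    counts_r = np.array([1, 0, 0, 3, 0])
    tags = RegionTags(start=11, counts_left=counts_l, counts_right=counts_r)
    params = RegionParams(mu=13.0, nu=5.0, rho=0.4)
    expected = 0.0
    for j, y in zip(range(11, 16), counts_l):
        lam = params.nu * density_left(float(j), params.mu, shape) + params.rho
        expected += y * math.log(lam) - lam - math.lgamma(y + 1)
    for j, y in zip(range(11, 16), counts_r):
        lam = params.nu * density_right(float(j), params.mu, shape) + params.rho
        expected += y * math.log(lam) - lam - math.lgamma(y + 1)
    assert region_log_likelihood(tags, params, shape) == pytest.approx(expected, abs=1e-12)


def test_masking_zero_count_position_adds_back_intensities(shape):
    counts = np.array([2, 0, 1, 0, 4, 0, 0, 1])
    tags = RegionTags(start=101, counts_left=counts.copy(), counts_right=counts[::-1].copy())
    params = RegionParams(mu=104.0, nu=20.0, rho=0.3)
    base = region_log_likelihood(tags, params, shape)
    # mask index 6 (zero count on both strands): removes two -lambda terms
    mask = np.zeros(8, dtype=bool)
    mask[6] = True
    masked = RegionTags(
        start=101,
        counts_left=counts.copy(),
        counts_right=counts[::-1].copy(),
        unmappable_left=mask,
        unmappable_right=mask,
    )
    j = 107.0
    lam_l = params.nu * density_left(j, params.mu, shape) + params.rho
    lam_r = params.nu * density_right(j, params.mu, shape) + params.rho
    assert region_log_likelihood(masked, params, shape) - base == pytest.approx(
        lam_l + lam_r, abs=1e-10
    )


def test_count_at_unmappable_position_is_rejected():
    with pytest.raises(ConsistencyError):
        RegionTags(
            start=1,
            counts_left=np.array([1, 0]),
            counts_right=np.array([0, 0]),
            unmappable_left=np.array([True, False]),
            unmappable_right=np.array([False, False]),
        )


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    offset=st.integers(min_value=-10_000, max_value=10_000),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_loglik_translation_invariance(offset, seed):
    """Shifting region start, mu, and every coordinate together leaves the
    log-likelihood unchanged."""
    shape = GlobalShape(sigma=40.0, beta=60.0)
    rng = np.random.default_rng(seed)
    counts_l = rng.poisson(0.5, 60)
    counts_r = rng.poisson(0.5, 60)
    tags = RegionTags(start=1000, counts_left=counts_l, counts_right=counts_r)
    params = RegionParams(mu=1030.0, nu=12.0, rho=0.2)
    shifted_params = RegionParams(mu=1030.0 + offset, nu=12.0, rho=0.2)
    assert region_log_likelihood(tags, params, shape) == pytest.approx(
        region_log_likelihood(tags.shifted(offset), shifted_params, shape), abs=1e-8
    )
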