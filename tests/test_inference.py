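"""Tests of per-region MLE, the LR binding test, the GOF test, SEs, and
global shape training."""

import math

import numpy as np
import pytest

from nextpeak.inference import (
    DEFAULT_SHAPE,
    RegionFit,
    _bare_fit,
    binding_lr_test,
    fit_global,
    fit_null,
    fit_region,
    goodness_of_fit_test,
    standard_errors,
)
from nextpeak.model import GlobalShape, RegionParams, RegionTags

from conftest import make_region


@pytest.mark.parametrize(
    "counts,width,expected_rho",
    [
        (np.ones(100, dtype=int), 100, 1.0),  # 200 tags / 200 slots
        (None, 75, 0.2),  # 30 tags over 2 x 75 mappable position-strands
    ],
)
def test_fit_null_closed_form(counts, width, expected_rho):
    if counts is None:
        counts_l = np.zeros(width, dtype=int)
        counts_l[:15] = 1
        counts_r = np.zeros(width, dtype=int)
        counts_r[-15:] = 1
    else:
        counts_l = counts_r = counts
    tags = RegionTags(start=1, counts_left=counts_l, counts_right=counts_r)
    rho, ll = fit_null(tags)
    assert rho == pytest.approx(expected_rho)
    assert np.isfinite(ll)


def test_fit_null_requires_mappable_positions():
    tags = RegionTags(
        start=1,
        counts_left=np.zeros(5, dtype=int),
        counts_right=np.zeros(5, dtype=int),
        unmappable_left=np.ones(5, dtype=bool),
        unmappable_right=np.ones(5, dtype=bool),
    )
    with pytest.raises(ValueError):
        fit_null(tags)


def test_null_loglik_never_exceeds_fit(shape):
    # nesting property over random fixtures: the unrestricted MLE dominates
    for seed in range(100):
        tags = make_region(seed, mu=80.0, nu=float(5 + 3 * (seed % 7)), rho=0.2, width=150)
        fit = fit_region(tags, shape)
        assert fit.null_loglik <= fit.loglik + 1e-8
        assert fit.lr_stat >= 0.0


def test_flat_background_recovery(shape):
    tags = make_region(404, mu=250.0, nu=0.0, rho=0.2, width=500)
    fit = fit_region(tags, shape)
    assert fit.params_hat.nu < 15.0  # at or near the boundary
    rho_se = math.sqrt(0.2 / tags.n_mappable)  # Poisson SE of the mean rate
    assert abs(fit.params_hat.rho - 0.2) < 3 * rho_se + fit.params_hat.nu / tags.width


def test_all_zero_counts_yields_null_fit(shape):
    tags = RegionTags(
        start=1, counts_left=np.zeros(50, dtype=int), counts_right=np.zeros(50, dtype=int)
    )
    fit = fit_region(tags, shape)
    assert fit.params_hat.nu == 0.0
    assert fit.lr_stat == 0.0 and fit.lr_pvalue == 1.0


def test_lr_test_chi2_reference(shape):
    fit = _bare_fit(RegionParams(mu=0, nu=0, rho=1.0), -10.0, 1.0, -10.0)
    lr, p = binding_lr_test(fit)
    assert lr == 0.0 and p == 1.0
    fit2 = _bare_fit(RegionParams(mu=0, nu=1, rho=1.0), -10.0 + 3.841459 / 2, 1.0, -10.0)
    _, p2 = binding_lr_test(fit2)
    assert p2 == pytest.approx(0.05, abs=1e-6)


def test_gof_zero_when_model_reproduces_counts(shape):
    # counts identically 1 and a fitted intensity of exactly 1 everywhere
    tags = RegionTags(
        start=1, counts_left=np.ones(30, dtype=int), counts_right=np.ones(30, dtype=int)
    )
    fit = _bare_fit(RegionParams(mu=15.0, nu=0.0, rho=1.0), 0.0, 1.0, 0.0)
    stat, df, p = goodness_of_fit_test(tags, fit, shape)
    assert stat == pytest.approx(0.0, abs=1e-10)
    assert df == 57
    assert p == pytest.approx(1.0)


def test_gof_deviance_matches_hand_computation(shape):
    # deviance on a 4-slot toy: y = [0,2,1,0] against lambda0 = [.5,1.5,1,.5]
    y = np.array([0.0, 2.0, 1.0, 0.0])
    lam = np.array([0.5, 1.5, 1.0, 0.5])
    expected = 2.0 * sum(
        (yi * math.log(yi / li) if yi > 0 else 0.0) - (yi - li) for yi, li in zip(y, lam)
    )
    from scipy.special import xlogy

    dev = 2.0 * float(np.sum(xlogy(y, y) - xlogy(y, lam) - (y - lam)))
    assert dev == pytest.approx(expected, abs=1e-10)


def test_gof_undefined_for_tiny_region(shape):
    tags = RegionTags(
        start=1, counts_left=np.array([2]), counts_right=np.array([1])
    )
    fit = _bare_fit(RegionParams(mu=1.0, nu=1.0, rho=0.5), 0.0, 1.5, 0.0)
    stat, df, p = goodness_of_fit_test(tags, fit, shape)
    assert df <= 0 and math.isnan(p)


def test_gof_equals_poisson_deviance_identity(shape):
    # algebraic identity: gof_stat == 2*sum[y log(y/lam) - (y - lam)] on any fixture
    tags = make_region(77, nu=150.0, rho=0.15, width=400, mu=200.0)
    fit = fit_region(tags, shape)
    from nextpeak.model import intensity

    pos = tags.positions().astype(float)
    dev = 0.0
    for counts, mask, strand in (
        (tags.counts_right, tags.unmappable_right, "right"),
        (tags.counts_left, tags.unmappable_left, "left"),
    ):
        y = counts[~mask].astype(float)
        lam = intensity(pos[~mask], strand, fit.params_hat, shape)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / lam), 0.0)
        dev += 2.0 * float(np.sum(term - (y - lam)))
    assert fit.gof_stat == pytest.approx(dev, rel=1e-10)


def test_standard_errors_on_converged_fit(shape):
    tags = make_region(5, nu=300.0, rho=0.1, width=500)
    fit = fit_region(tags, shape)
    assert fit.converged
    assert fit.covariance is not None
    np.testing.assert_allclose(fit.covariance, fit.covariance.T, atol=1e-8)
    assert np.all(np.diag(fit.covariance) > 0)
    se_mu, se_nu, se_rho = standard_errors(fit)
    assert se_mu > 0 and se_nu > 0 and se_rho > 0


def test_se_mu_calibrated_against_empirical_sd(shape):
    # the reported SE of mu should track the sampling SD of mu_hat
    mus, ses = [], []
    for seed in range(120):
        tags = make_region(60_000 + seed, nu=200.0, rho=0.1, width=500)
        fit = fit_region(tags, shape)
        if fit.covariance is not None:
            mus.append(fit.params_hat.mu)
            ses.append(fit.se_mu)
    sd = np.std(mus)
    assert abs(sd - np.mean(ses)) < 0.25 * sd


def test_se_mu_shrinks_with_tag_depth(shape):
    def mean_se(nu, base):
        vals = []
        for seed in range(20):
            fit = fit_region(make_region(base + seed, nu=nu, rho=0.1, width=500), shape)
            if fit.covariance is not None:
                vals.append(fit.se_mu)
        return np.mean(vals)

    assert mean_se(800.0, 71_000) < mean_se(100.0, 72_000)


def test_fit_translation_equivariance(shape):
    tags = make_region(9, nu=250.0, rho=0.1, width=500)
    fit = fit_region(tags, shape)
    delta = 12_345
    fit2 = fit_region(tags.shifted(delta), shape)
    assert fit2.params_hat.mu - fit.params_hat.mu == pytest.approx(delta, abs=1e-3)
    assert fit2.params_hat.nu == pytest.approx(fit.params_hat.nu, abs=1e-3)
    assert fit2.params_hat.rho == pytest.approx(fit.params_hat.rho, abs=1e-6)
    assert fit2.lr_stat == pytest.approx(fit.lr_stat, abs=1e-4)
    assert fit2.gof_stat == pytest.approx(fit.gof_stat, abs=1e-4)


def test_censoring_compensation(shape):
    """With 40% of positions censored the estimated binding strength still
    recovers the truth, exceeding the observed tag count."""
    nus, observed = [], []
    for seed in range(60):
        tags = make_region(80_000 + seed, nu=200.0, rho=0.1, width=500,
                           unmappable_fraction=0.4)
        fit = fit_region(tags, shape)
        nus.append(fit.params_hat.nu)
        observed.append(tags.total_tags / 2.0)
    assert np.mean(nus) == pytest.approx(200.0, rel=0.1)
    assert np.mean(nus) > np.mean(observed)  # compensates for censored tags


def test_fit_global_defaults_without_training():
    shape = fit_global([], [])
    assert (shape.sigma, shape.beta) == (30.0, 50.0)
    assert (DEFAULT_SHAPE.sigma, DEFAULT_SHAPE.beta) == (30.0, 50.0)


def test_fit_global_recovers_shape():
    regions, anchors = [], []
    for seed in range(50):
        tags = make_region(90_000 + seed, mu=500.0, nu=300.0, rho=0.1, width=1000)
        regions.append(tags)
        anchors.append(500.0)
    shape = fit_global(regions, anchors)
    assert shape.sigma == pytest.approx(40.0, rel=0.10)
    assert shape.beta == pytest.approx(60.0, rel=0.10)


def test_profiled_objective_peaks_at_truth():
    from nextpeak.inference import _prepare, _profiled_region_ll

    regions = [make_region(95_000 + s, mu=500.0, nu=300.0, rho=0.1, width=1000)
               for s in range(20)]

    def objective(sigma, beta):
        return sum(
            _profiled_region_ll(_prepare(t), 500.0, sigma, beta, 250.0, 0.1)
            for t in regions
        )

    assert objective(40.0, 60.0) >= objective(60.0, 90.0)
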