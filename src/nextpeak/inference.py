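"""Maximum-likelihood inference for the two-peak model.

Per region: profile MLE of (mu, nu, rho) with the global shape (sigma, beta)
held fixed, asymptotic standard errors from the observed information, a
likelihood-ratio test of binding (H0: nu = 0, chi^2 with 1 df) and a
saturated-model goodness-of-fit test (Poisson deviance).  Globally: (sigma,
beta) trained by maximizing the summed region likelihood with each region's mu
anchored at a known motif site and (nu, rho) profiled out.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, xlogy

from .model import (
    ConsistencyError,
    GlobalShape,
    RegionParams,
    RegionTags,
    _g_and_dg,
    region_log_likelihood,
)

__all__ = [
    "RegionFit",
    "fit_region",
    "fit_null",
    "binding_lr_test",
    "goodness_of_fit_test",
    "fit_global",
    "standard_errors",
    "DEFAULT_SHAPE",
]

#: Shape used when no motif-anchored training data are available.
DEFAULT_SHAPE = GlobalShape(sigma=30.0, beta=50.0)

# central-difference steps for the observed-information Hessian: bp, tags, tags/bp
_HESS_STEPS = (0.01, 0.1, 1e-4)


@dataclass
class RegionFit:
    """Per-region estimates, covariance, and both test results."""

    params_hat: RegionParams
    loglik: float
    null_rho: float
    null_loglik: float
    lr_stat: float
    lr_pvalue: float
    gof_stat: float
    gof_df: int
    gof_pvalue: float  # NaN when gof_df <= 0 (test undefined)
    covariance: np.ndarray | None = None  # 3x3, order (mu, nu, rho); None if singular
    converged: bool = True

    @property
    def se_mu(self) -> float:
        return self._se(0)

    @property
    def se_nu(self) -> float:
        return self._se(1)

    @property
    def se_rho(self) -> float:
        return self._se(2)

    def _se(self, i: int) -> float:
        if self.covariance is None:
            return float("nan")
        v = self.covariance[i, i]
        return math.sqrt(v) if v > 0 else float("nan")


def _prepare(tags: RegionTags):
    """Mappable positions and counts per strand, as float arrays."""
    pos = tags.positions().astype(float)
    mR = ~tags.unmappable_right
    mL = ~tags.unmappable_left
    return (
        pos[mR],
        tags.counts_right[mR].astype(float),
        pos[mL],
        tags.counts_left[mL].astype(float),
    )


def _nll_grad(theta, posR, yR, posL, yL, sigma, beta):
    """Negative log-likelihood (without the y! constant) and its gradient."""
    mu, nu, rho = theta
    gR, dgR = _g_and_dg(posR - mu, sigma, beta)
    gL, dgL = _g_and_dg(mu - posL, sigma, beta)
    lamR = nu * gR + rho
    lamL = nu * gL + rho
    ll = np.sum(xlogy(yR, lamR) - lamR) + np.sum(xlogy(yL, lamL) - lamL)
    with np.errstate(divide="ignore", invalid="ignore"):
        wR = np.where(lamR > 0, yR / np.maximum(lamR, 1e-300) - 1.0, 0.0)
        wL = np.where(lamL > 0, yL / np.maximum(lamL, 1e-300) - 1.0, 0.0)
    # d lamR / d mu = -nu g'(posR - mu); d lamL / d mu = +nu g'(mu - posL)
    dmu = -nu * np.sum(wR * dgR) + nu * np.sum(wL * dgL)
    dnu = np.sum(wR * gR) + np.sum(wL * gL)
    drho = np.sum(wR) + np.sum(wL)
    return -ll, -np.array([dmu, dnu, drho])


def _default_init(tags: RegionTags) -> RegionParams:
    """Deterministic, scale-free starting point.

    mu0: midpoint between the modes of 20-bp-smoothed strand profiles;
    rho0: 25th percentile of mappable per-position counts (robust to the peak);
    nu0: excess tags over background, split per strand.
    """
    pos = tags.positions()
    kernel = np.ones(20) / 20.0

    def smoothed_mode(counts, mask):
        c = np.where(mask, 0.0, counts.astype(float))
        if c.sum() == 0:
            return float(pos[len(pos) // 2])
        s = np.convolve(c, kernel, mode="same")
        return float(pos[int(np.argmax(s))])

    mode_l = smoothed_mode(tags.counts_left, tags.unmappable_left)
    mode_r = smoothed_mode(tags.counts_right, tags.unmappable_right)
    mu0 = 0.5 * (mode_l + mode_r)
    mappable_counts = np.concatenate(
        [
            tags.counts_left[~tags.unmappable_left],
            tags.counts_right[~tags.unmappable_right],
        ]
    )
    rho0 = float(np.percentile(mappable_counts, 25)) if mappable_counts.size else 0.0
    rho0 = max(rho0, tags.total_tags / max(tags.n_mappable, 1) * 0.1, 1e-4)
    nu0 = max(tags.total_tags - tags.width * rho0 * 2.0, 1.0) / 2.0
    return RegionParams(mu=mu0, nu=nu0, rho=rho0)


def fit_null(tags: RegionTags) -> tuple[float, float]:
    """Closed-form MLE under nu = 0: constant Poisson intensity.

    Returns (rho_hat_null, loglik_null) with
    rho_hat_null = total mappable tags / number of mappable position-strand
    pairs.  mu is unidentifiable under the restriction and is not reported.
    """
    n_map = tags.n_mappable
    if n_map == 0:
        raise ValueError("region has no mappable positions")
    total = tags.total_tags
    rho = total / n_map
    const = float(
        np.sum(gammaln(tags.counts_left[~tags.unmappable_left] + 1.0))
        + np.sum(gammaln(tags.counts_right[~tags.unmappable_right] + 1.0))
    )
    ll = (total * math.log(rho) if total > 0 else 0.0) - rho * n_map - const
    return rho, ll


def _observed_information(
    tags: RegionTags, shape: GlobalShape, params: RegionParams
) -> np.ndarray | None:
    """Negative Hessian of the log-likelihood at ``params`` by central
    differences; None when the boundary (nu near 0) prevents a symmetric
    stencil or a step would leave the parameter space."""
    theta = np.array([params.mu, params.nu, params.rho], dtype=float)
    h = np.array(_HESS_STEPS)
    if theta[1] < h[1] or theta[2] < h[2]:
        return None
    posR, yR, posL, yL = _prepare(tags)

    def f(t):
        return -_nll_grad(t, posR, yR, posL, yL, shape.sigma, shape.beta)[0]

    hess = np.empty((3, 3))
    f0 = f(theta)
    for i in range(3):
        ei = np.zeros(3)
        ei[i] = h[i]
        hess[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, 3):
            ej = np.zeros(3)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return -hess


def _covariance_from_information(info: np.ndarray | None) -> np.ndarray | None:
    if info is None:
        return None
    try:
        eigvals = np.linalg.eigvalsh(info)
    except np.linalg.LinAlgError:
        return None
    if np.any(eigvals <= 0):
        return None
    cov = np.linalg.inv(info)
    return 0.5 * (cov + cov.T)


def standard_errors(fit: RegionFit) -> tuple[float, float, float]:
    """Asymptotic standard errors (se_mu, se_nu, se_rho) from the inverse
    observed information; NaN triple when the information matrix was singular,
    indefinite, or the estimate sat on the nu >= 0 boundary."""
    return fit.se_mu, fit.se_nu, fit.se_rho


def binding_lr_test(fit: RegionFit) -> tuple[float, float]:
    """Likelihood-ratio test of binding, H0: nu = 0.

    lambda = -2 log L(theta_null)/L(theta_hat), referred to chi^2 with 1 df
    (conservative at the nu >= 0 boundary).  Clipped at zero.
    """
    lr = max(0.0, 2.0 * (fit.loglik - fit.null_loglik))
    return lr, float(stats.chi2.sf(lr, df=1))


def goodness_of_fit_test(
    tags: RegionTags, fit: RegionFit, shape: GlobalShape
) -> tuple[float, int, float]:
    """Saturated-vs-model LR test: the Poisson deviance of the fitted
    intensities against one free intensity per mappable position per strand.

    Returns (gof_stat, df, pvalue); df = mappable position-strand pairs - 3,
    pvalue is NaN when df <= 0 (test undefined).  A small p-value flags counts
    the single-event model cannot explain (PCR spikes, multiple binding).
    """
    posR, yR, posL, yL = _prepare(tags)
    p = fit.params_hat
    gR, _ = _g_and_dg(posR - p.mu, shape.sigma, shape.beta)
    gL, _ = _g_and_dg(p.mu - posL, shape.sigma, shape.beta)
    dev = 0.0
    for y, lam in ((yR, p.nu * gR + p.rho), (yL, p.nu * gL + p.rho)):
        # 0 log 0 := 0 (saturated MLE at y = 0)
        dev += 2.0 * float(np.sum(xlogy(y, y) - xlogy(y, lam) - (y - lam)))
    df = int(len(yR) + len(yL) - 3)
    if df <= 0:
        return dev, df, float("nan")
    return dev, df, float(stats.chi2.sf(dev, df=df))


def fit_region(
    tags: RegionTags, shape: GlobalShape, init: RegionParams | None = None
) -> RegionFit:
    """Profile MLE of (mu, nu, rho) for one region, with tests and SEs.

    Bounded quasi-Newton (L-BFGS-B with analytic gradient) from a deterministic
    initialization plus a coarse mu scan; the nu = 0 boundary profile (the
    closed-form null fit) is always evaluated as well, so the returned fit is
    never worse than the null.  Non-convergence is flagged, not raised.
    """
    null_rho, null_ll = fit_null(tags)
    if tags.total_tags == 0:
        params = RegionParams(mu=float(tags.start + tags.width // 2), nu=0.0, rho=null_rho)
        gof_stat, gof_df, gof_p = goodness_of_fit_test(
            tags, _bare_fit(params, null_ll, null_rho, null_ll), shape
        )
        return RegionFit(
            params_hat=params,
            loglik=null_ll,
            null_rho=null_rho,
            null_loglik=null_ll,
            lr_stat=0.0,
            lr_pvalue=1.0,
            gof_stat=gof_stat,
            gof_df=gof_df,
            gof_pvalue=gof_p,
            covariance=None,
            converged=True,
        )

    posR, yR, posL, yL = _prepare(tags)
    sigma, beta = shape.sigma, shape.beta
    args = (posR, yR, posL, yL, sigma, beta)

    # mu is confined to the region: outside it the density barely overlaps the
    # observed positions and nu loses identifiability (a huge nu times a
    # vanishing tail can mimic a background tilt)
    p0 = init if init is not None else _default_init(tags)
    bounds = [
        (float(tags.start), float(tags.end)),
        (0.0, 10.0 * tags.total_tags + 10.0),
        (1e-10, max(10.0 * tags.total_tags / max(tags.n_mappable, 1), 1.0)),
    ]

    # coarse mu scan to dodge local optima of the location profile
    mu_grid = np.arange(tags.start, tags.end + 1, max(5, tags.width // 64), dtype=float)
    scan = [
        _nll_grad((m, p0.nu, p0.rho), *args)[0] for m in mu_grid
    ]
    mu_best = float(mu_grid[int(np.argmin(scan))])
    starts = [np.array([p0.mu, p0.nu, p0.rho])]
    if abs(mu_best - p0.mu) > 1.0:
        starts.append(np.array([mu_best, p0.nu, p0.rho]))

    best = None
    converged = False
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _nll_grad,
            x0,
            args=args,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    mu_hat, nu_hat, rho_hat = best.x
    params = RegionParams(mu=float(mu_hat), nu=float(nu_hat), rho=float(rho_hat))
    ll = region_log_likelihood(tags, params, shape)
    if ll < null_ll:  # boundary profile wins: fall back to the null fit
        params = RegionParams(mu=float(mu_hat), nu=0.0, rho=null_rho)
        ll = null_ll
        converged = True

    fit = _bare_fit(params, ll, null_rho, null_ll)
    fit.converged = converged
    fit.lr_stat, fit.lr_pvalue = binding_lr_test(fit)
    fit.gof_stat, fit.gof_df, fit.gof_pvalue = goodness_of_fit_test(tags, fit, shape)
    fit.covariance = _covariance_from_information(
        _observed_information(tags, shape, params)
    )
    return fit


def _bare_fit(params, ll, null_rho, null_ll) -> RegionFit:
    return RegionFit(
        params_hat=params,
        loglik=ll,
        null_rho=null_rho,
        null_loglik=null_ll,
        lr_stat=0.0,
        lr_pvalue=1.0,
        gof_stat=0.0,
        gof_df=0,
        gof_pvalue=float("nan"),
    )


def _profiled_region_ll(tags_data, anchor, sigma, beta, nu0, rho0) -> float:
    """Max over (nu, rho) of the region log-likelihood with mu fixed at the
    motif anchor.  Concave in (nu, rho) since lambda is linear in them."""
    posR, yR, posL, yL = tags_data
    gR, _ = _g_and_dg(posR - anchor, sigma, beta)
    gL, _ = _g_and_dg(anchor - posL, sigma, beta)

    def nll(x):
        nu, rho = x
        lamR = nu * gR + rho
        lamL = nu * gL + rho
        ll = np.sum(xlogy(yR, lamR) - lamR) + np.sum(xlogy(yL, lamL) - lamL)
        wR = yR / np.maximum(lamR, 1e-300) - 1.0
        wL = yL / np.maximum(lamL, 1e-300) - 1.0
        grad = np.array(
            [np.sum(wR * gR) + np.sum(wL * gL), np.sum(wR) + np.sum(wL)]
        )
        return -ll, -grad

    res = optimize.minimize(
        nll,
        np.array([nu0, rho0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None), (1e-10, None)],
        options={"ftol": 1e-12},
    )
    return -float(res.fun)


def fit_global(
    training: list[RegionTags],
    anchors: list[float],
    defaults: GlobalShape = DEFAULT_SHAPE,
) -> GlobalShape:
    """Train (sigma, beta) on motif-anchored regions.

    Maximizes the summed region log-likelihood over (sigma, beta) with each
    region's mu fixed at its anchor (a motif-site center) and (nu, rho)
    profiled out per region.  With no training data, returns ``defaults``
    (sigma = 30, beta = 50).
    """
    if len(training) != len(anchors):
        raise ValueError("training regions and anchors must align")
    if not training:
        return defaults

    prepared = []
    for tags, anchor in zip(training, anchors):
        p0 = _default_init(tags)
        prepared.append((_prepare(tags), float(anchor), p0.nu, p0.rho))

    def neg_total(log_sb):
        s, b = np.exp(log_sb)
        return -sum(
            _profiled_region_ll(data, anchor, s, b, nu0, rho0)
            for data, anchor, nu0, rho0 in prepared
        )

    res = optimize.minimize(
        neg_total,
        np.log([defaults.sigma, defaults.beta]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    s, b = np.exp(res.x)
    if not res.success:
        warnings.warn("global shape training did not fully converge", RuntimeWarning)
    return GlobalShape(sigma=float(s), beta=float(b))
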