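"""Normal-exponential two-peak (NEXT-peak) tag density and the censored Poisson
region likelihood.

The generative picture: a transcription factor is cross-linked to DNA at a
latent coordinate xi ~ N(mu, sigma^2); sonication breaks the DNA at an
exponentially distributed distance (mean beta) downstream of the cross-link, so
the 5' end of a reverse-strand ("right") tag lands at x = xi + Exp(beta). The
marginal density of x is the exponentially modified Gaussian

    f_R(x | mu, sigma, beta)
        = Phi((x - mu)/sigma - sigma/beta)
          * (1/beta) * exp(-(x - mu)/beta + sigma^2 / (2 beta^2)),

and forward-strand ("left") tags follow the mirror image
f_L(mu - z) = f_R(mu + z).  Observed per-position tag counts on each strand are
modelled as independent Poisson variables with intensity

    lambda_j = nu * f(j) + rho,

where nu is the expected tag count per strand contributed by one binding event
and rho the locally uniform background rate (tags per bp per strand).
Positions whose tag sequence is not unique in the genome (the unmappable set)
cannot receive tags and are censored: they contribute nothing to the
likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, log_ndtr, xlogy

__all__ = [
    "GlobalShape",
    "RegionParams",
    "RegionTags",
    "density_right",
    "density_left",
    "log_density_right",
    "log_density_left",
    "intensity",
    "region_log_likelihood",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GlobalShape:
    """Genome-wide shape parameters shared by all candidate regions.

    Parameters
    ----------
    sigma : float
        Standard deviation (bp) of the cross-link location around the binding
        site center.
    beta : float
        Mean (bp) of the exponential cross-link-to-fragment-end distance.
    """

    sigma: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be finite and > 0, got {self.sigma}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")


@dataclass(frozen=True)
class RegionParams:
    """Per-region parameters: site center mu (bp), binding intensity nu
    (expected tags per strand per event), background rho (tags/bp/strand).

    rho == 0 is admitted only for the degenerate all-zero-count fit.
    """

    mu: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (np.isfinite(self.nu) and self.nu >= 0):
            raise ValueError(f"nu must be finite and >= 0, got {self.nu}")
        if not (np.isfinite(self.rho) and self.rho >= 0):
            raise ValueError(f"rho must be finite and >= 0, got {self.rho}")


class ConsistencyError(ValueError):
    """Raised when tag counts contradict the unmappable mask."""


@dataclass
class RegionTags:
    """Per-position tag counts for one candidate region, both strands.

    Coordinates are 1-based inclusive; position ``start + k`` corresponds to
    index ``k`` of each vector.  ``unmappable_*`` mark censored positions
    (members of the unmappable set), at which counts must be zero.
    """

    start: int
    counts_left: np.ndarray
    counts_right: np.ndarray
    unmappable_left: np.ndarray | None = None
    unmappable_right: np.ndarray | None = None
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.counts_left = np.asarray(self.counts_left)
        self.counts_right = np.asarray(self.counts_right)
        w = self.counts_left.shape[0]
        if w < 1:
            raise ValueError("region width must be >= 1")
        if self.counts_right.shape[0] != w:
            raise ValueError("strand count vectors must have equal length")
        for name in ("counts_left", "counts_right"):
            c = getattr(self, name)
            if c.ndim != 1 or np.any(c < 0) or np.any(c != np.floor(c)):
                raise ValueError(f"{name} must be non-negative integers")
            setattr(self, name, c.astype(np.int64))
        if self.unmappable_left is None:
            self.unmappable_left = np.zeros(w, dtype=bool)
        if self.unmappable_right is None:
            self.unmappable_right = np.zeros(w, dtype=bool)
        self.unmappable_left = np.asarray(self.unmappable_left, dtype=bool)
        self.unmappable_right = np.asarray(self.unmappable_right, dtype=bool)
        if self.unmappable_left.shape[0] != w or self.unmappable_right.shape[0] != w:
            raise ValueError("unmappable masks must match region width")
        self.validate_censoring()

    def validate_censoring(self) -> None:
        if np.any(self.counts_left[self.unmappable_left] > 0) or np.any(
            self.counts_right[self.unmappable_right] > 0
        ):
            raise ConsistencyError("non-zero tag count at an unmappable position")

    @property
    def width(self) -> int:
        return int(self.counts_left.shape[0])

    @property
    def end(self) -> int:
        return self.start + self.width - 1

    def positions(self) -> np.ndarray:
        """1-based genomic coordinates of the region's positions."""
        return np.arange(self.start, self.start + self.width, dtype=np.int64)

    @property
    def total_tags(self) -> int:
        return int(self.counts_left.sum() + self.counts_right.sum())

    @property
    def n_mappable(self) -> int:
        """Number of mappable position-strand pairs."""
        return int((~self.unmappable_left).sum() + (~self.unmappable_right).sum())

    def shifted(self, delta: int) -> "RegionTags":
        """The same region translated by ``delta`` bp."""
        return RegionTags(
            start=self.start + int(delta),
            counts_left=self.counts_left.copy(),
            counts_right=self.counts_right.copy(),
            unmappable_left=self.unmappable_left.copy(),
            unmappable_right=self.unmappable_right.copy(),
            chrom=self.chrom,
        )


def _check_finite(x: np.ndarray | float, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _log_g(t: np.ndarray, sigma: float, beta: float) -> np.ndarray:
    # log density of the centered ex-Gaussian at offset t = x - mu, computed
    # entirely in log space: the exp factor overflows for t << 0 otherwise.
    z = t / sigma - sigma / beta
    return log_ndtr(z) - math.log(beta) - t / beta + 0.5 * (sigma / beta) ** 2


def _g_and_dg(t: np.ndarray, sigma: float, beta: float):
    """Centered density g(t) and its derivative g'(t)."""
    z = t / sigma - sigma / beta
    log_a = -t / beta + 0.5 * (sigma / beta) ** 2 - math.log(beta)
    g = np.exp(log_ndtr(z) + log_a)
    dg = -g / beta + np.exp(log_a - 0.5 * z * z) / (sigma * _SQRT_2PI)
    return g, dg


def log_density_right(x, mu: float, shape: GlobalShape) -> np.ndarray:
    """Log of the reverse-strand ("right") tag density at coordinate(s) x."""
    x = _check_finite(x, "x")
    mu = float(_check_finite(mu, "mu"))
    return _log_g(x - mu, shape.sigma, shape.beta)


def log_density_left(x, mu: float, shape: GlobalShape) -> np.ndarray:
    """Log of the forward-strand ("left") tag density: the mirror image of the
    right density around mu, f_L(x) = f_R(2 mu - x)."""
    x = _check_finite(x, "x")
    mu = float(_check_finite(mu, "mu"))
    return _log_g(mu - x, shape.sigma, shape.beta)


def density_right(x, mu: float, shape: GlobalShape) -> np.ndarray:
    """Reverse-strand tag density f_R(x | mu, sigma, beta), per bp."""
    return np.exp(log_density_right(x, mu, shape))


def density_left(x, mu: float, shape: GlobalShape) -> np.ndarray:
    """Forward-strand tag density f_L(x | mu, sigma, beta), per bp."""
    return np.exp(log_density_left(x, mu, shape))


_DENSITY = {"left": density_left, "right": density_right}


def intensity(j, strand: str, params: RegionParams, shape: GlobalShape) -> np.ndarray:
    """Expected tag count at position(s) j on ``strand``:
    lambda_j = nu * f(j) + rho."""
    if strand not in _DENSITY:
        raise ValueError(f"strand must be 'left' or 'right', got {strand!r}")
    return params.nu * _DENSITY[strand](j, params.mu, shape) + params.rho


def region_log_likelihood(
    tags: RegionTags, params: RegionParams, shape: GlobalShape
) -> float:
    """Censored Poisson log-likelihood of a region's counts on both strands.

    Sums the Poisson log-pmf log(e^{-lambda} lambda^y / y!) over mappable
    positions only; unmappable (censored) positions contribute nothing.
    """
    tags.validate_censoring()
    pos = tags.positions().astype(float)
    ll = 0.0
    for counts, mask, strand in (
        (tags.counts_right, tags.unmappable_right, "right"),
        (tags.counts_left, tags.unmappable_left, "left"),
    ):
        m = ~mask
        if not np.any(m):
            continue
        lam = intensity(pos[m], strand, params, shape)
        y = counts[m]
        ll += float(np.sum(xlogy(y, lam) - lam - gammaln(y + 1.0)))
    return ll
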