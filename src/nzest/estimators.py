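"""Sample-based estimators of a binned distribution.

Six estimators are provided; all but plain bin counting guarantee strictly
positive probability in every bin:

``bincount`` (BC)
    Normalized frequencies ``x_k / n``; may contain exact zeros.
``addone`` (AO)
    One counter is added to every *empty* bin before normalizing, so the
    impact of the correction shrinks as ``1/n``.
``bayes`` (BAY)
    Posterior mean of a Dirichlet-multinomial model with a flat Dirichlet
    prior (``α`` pseudo-counts in every bin, default 1):
    ``(x_k + α) / (n + Kα)``.
``addp`` (AP)
    A fixed small probability mass (default 1e-4) is added to every
    zero-probability bin of the normalized histogram, then the vector is
    renormalized; the correction is virtually independent of ``n``.
``kds`` (KDS)
    Gaussian kernel-density smoothing on the bounded support: each
    observation is placed at its bin's representative outcome value, kernels
    are truncated to the support and renormalized, the mixture is integrated
    over the bin edges, and the bandwidth is grown from ``kds_bw0`` in
    ``kds_bw_step`` increments until every bin probability is strictly
    positive in double precision.
``nonzero`` (NZ)
    Per bin, the exact Clopper-Pearson confidence interval for the
    bin-occupation probability is computed at the chosen level; the interval
    midpoints ``m_k = (lower_k + upper_k)/2`` are normalized by their sum.
    Midpoints are strictly positive, so the estimate is too; with no data it
    is exactly uniform (a maximum-entropy default), and it converges to the
    bin-count estimate as ``n`` grows.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.special import ndtr

from .clopper_pearson import cp_bounds
from .distributions import BinnedDistribution, SampleCounts

__all__ = [
    "EstimatorSpec",
    "METHODS",
    "estimate",
    "bincount_estimate",
    "addone_estimate",
    "bayes_estimate",
    "addp_estimate",
    "kds_estimate",
    "nonzero_estimate",
]

logger = logging.getLogger(__name__)

METHODS = ("bincount", "addone", "bayes", "addp", "kds", "nonzero")

#: Conventional short codes accepted as aliases.
ALIASES = {"bc": "bincount", "ao": "addone", "bay": "bayes", "ap": "addp", "nz": "nonzero"}


@dataclasses.dataclass(frozen=True)
class EstimatorSpec:
    """An estimator choice plus its tuning parameters.

    level
        Confidence level of the Clopper-Pearson intervals (nonzero method).
    add_mass
        Probability mass added to each empty bin (addp method).
    prior_count
        Flat Dirichlet prior parameter α (bayes method).
    kds_bw0 / kds_bw_step / kds_bw_cap
        Initial bandwidth, increment, and safety cap of the KDS bandwidth
        search.
    """

    method: str
    level: float = 0.95
    add_mass: float = 1e-4
    prior_count: float = 1.0
    kds_bw0: float = 0.05
    kds_bw_step: float = 0.001
    kds_bw_cap: float = 5.0

    def __post_init__(self) -> None:
        m = ALIASES.get(self.method.lower(), self.method.lower())
        if m not in METHODS:
            raise ValueError(f"unknown estimation method {self.method!r}; choose from {METHODS}")
        object.__setattr__(self, "method", m)
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"confidence level must be in (0, 1), got {self.level}")
        for name in ("add_mass", "prior_count", "kds_bw0", "kds_bw_step", "kds_bw_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def estimate(spec: EstimatorSpec, counts: SampleCounts) -> BinnedDistribution:
    """Dispatch to the estimator named by ``spec.method``."""
    m = spec.method
    if m == "bincount":
        return bincount_estimate(counts)
    if m == "addone":
        return addone_estimate(counts)
    if m == "bayes":
        return bayes_estimate(counts, spec.prior_count)
    if m == "addp":
        return addp_estimate(counts, spec.add_mass)
    if m == "kds":
        dist, bw = kds_estimate(
            counts, bw0=spec.kds_bw0, bw_step=spec.kds_bw_step, bw_cap=spec.kds_bw_cap
        )
        return dist
    return nonzero_estimate(counts, spec.level)


def bincount_estimate(counts: SampleCounts) -> BinnedDistribution:
    """Normalized frequencies ``x_k / n`` (may contain exact zeros)."""
    if counts.n == 0:
        raise ValueError("bincount estimate is undefined for an empty sample (n = 0)")
    return BinnedDistribution(counts.grid, counts.counts / counts.n)


def addone_estimate(counts: SampleCounts) -> BinnedDistribution:
    """Fill each empty bin with one counter, then normalize."""
    c = counts.counts.astype(float)
    filled = c + (c == 0)
    return BinnedDistribution(counts.grid, filled / filled.sum())


def bayes_estimate(counts: SampleCounts, prior_count: float = 1.0) -> BinnedDistribution:
    """Dirichlet-multinomial posterior mean with a flat prior of ``α`` per bin."""
    if prior_count <= 0:
        raise ValueError(f"prior_count must be strictly positive, got {prior_count}")
    c = counts.counts + prior_count
    return BinnedDistribution(counts.grid, c / c.sum())


def addp_estimate(counts: SampleCounts, add_mass: float = 1e-4) -> BinnedDistribution:
    """Add a fixed probability mass to each zero bin of the histogram pdf."""
    if add_mass <= 0:
        raise ValueError(f"add_mass must be strictly positive, got {add_mass}")
    q = bincount_estimate(counts).probs.copy()
    zero = q == 0.0
    q[zero] = add_mass
    return BinnedDistribution(counts.grid, q / q.sum())


def kds_estimate(
    counts: SampleCounts,
    bw0: float = 0.05,
    bw_step: float = 0.001,
    bw_cap: float = 5.0,
) -> tuple[BinnedDistribution, float]:
    """Bounded-support Gaussian kernel smoothing with a grown bandwidth.

    Each observation is embedded at its bin's representative outcome value.
    Every kernel is truncated to the support and renormalized; bin masses are
    CDF differences over the bin edges.  Starting from ``bw0`` the bandwidth
    is increased in ``bw_step`` increments until every bin mass is strictly
    positive (in double precision), which guarantees a nonzero estimate while
    avoiding unnecessary smoothing.

    Returns the estimate together with the bandwidth actually used.
    """
    if counts.n == 0:
        raise ValueError("KDS estimate is undefined for an empty sample (n = 0)")
    grid = counts.grid
    occupied = counts.counts > 0
    locs = np.asarray(grid.values)[occupied]
    weights = counts.counts[occupied] / counts.n
    edges = grid.edges

    # Evaluate candidate bandwidths in growing chunks; the first all-positive
    # bandwidth (lowest wins) is used.
    start = 0
    n_steps = int(np.floor((bw_cap - bw0) / bw_step)) + 1
    chunk = 1
    while start < n_steps:
        stop = min(start + chunk, n_steps)
        hs = bw0 + bw_step * np.arange(start, stop)
        z = (edges[None, None, :] - locs[None, :, None]) / hs[:, None, None]
        cdf = ndtr(z)
        total = cdf[..., -1] - cdf[..., 0]  # truncation renormalization per kernel
        mass = (cdf[..., 1:] - cdf[..., :-1]) / total[..., None]
        probs = np.einsum("j,hjk->hk", weights, mass)
        ok = np.all(probs > 0.0, axis=1)
        if np.any(ok):
            i = int(np.argmax(ok))
            p = probs[i]
            bw = float(hs[i])
            logger.debug("KDS bandwidth search settled at h=%.4f", bw)
            return BinnedDistribution(grid, p / p.sum()), bw
        start = stop
        chunk = min(chunk * 8, 512)
    raise RuntimeError(
        f"KDS bandwidth search reached the cap {bw_cap} without achieving "
        "strictly positive bin probabilities"
    )


def nonzero_estimate(counts: SampleCounts, level: float = 0.95) -> BinnedDistribution:
    """Normalized Clopper-Pearson interval midpoints (the nonzero method).

    For each bin the exact binomial confidence interval of the bin-occupation
    probability is computed at ``level``; the estimate is the vector of
    interval midpoints normalized by its sum.  An empty sample (n = 0) yields
    the exact uniform distribution — the maximum-entropy default.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    k = counts.grid.k
    if counts.n == 0:
        return BinnedDistribution(counts.grid, np.full(k, 1.0 / k))
    lower, upper = cp_bounds(counts.counts, counts.n, level)
    m = 0.5 * (lower + upper)
    logger.debug("NZ normalization constant sum(m_k) = %.6f", m.sum())
    return BinnedDistribution(counts.grid, m / m.sum())
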