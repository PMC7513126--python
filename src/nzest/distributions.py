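"""Bin grids, distribution/count containers, sampling, and test-distribution fixtures.

The package works with discrete (binned) distributions over ``K`` equal-width
bins.  A :class:`BinGrid` describes the binning of a bounded numeric support;
:class:`BinnedDistribution` holds a probability vector over the bins, and
:class:`SampleCounts` holds a histogram of observations.

The canonical benchmark grid has nine bins over ``[0, 9.001]`` with the
discrete outcomes located at the integer values 1..9 (each integer sits just
below the upper edge of its bin; the 0.001 overhang keeps the largest outcome
strictly inside the support, which matters for bounded-support kernel
smoothing).  Grids built directly by users default to bin-center
representative values instead.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

__all__ = [
    "BinGrid",
    "BinnedDistribution",
    "SampleCounts",
    "default_grid",
    "make_test_distribution",
    "sample_counts",
    "histogram_from_values",
    "TEST_DISTRIBUTIONS",
    "IRREGULAR_PROBS",
]

#: Probability below which a fixture entry is treated as an exact zero.
ZERO_CLAMP = 1e-12

#: Hand-authored irregular 9-bin shape with one exact-zero bin (index 4).
IRREGULAR_PROBS = (0.08, 0.25, 0.02, 0.18, 0.0, 0.12, 0.30, 0.01, 0.04)

#: Names accepted by :func:`make_test_distribution`.
TEST_DISTRIBUTIONS = (
    "uniform",
    "dirac",
    "normal_narrow",
    "normal_wide",
    "bimodal",
    "irregular",
    "demo6",
)


@dataclasses.dataclass(frozen=True)
class BinGrid:
    """``k`` equal-width, half-open bins covering ``[support_lo, support_hi)``.

    The last bin is closed at ``support_hi``.  ``values`` are the
    representative numeric outcome per bin, used when a point embedding of a
    discrete observation is required (kernel-density smoothing); they default
    to the bin centers.
    """

    k: int
    support_lo: float
    support_hi: float
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"number of bins must be >= 1, got {self.k}")
        if not self.support_hi > self.support_lo:
            raise ValueError(
                f"support_hi ({self.support_hi}) must exceed support_lo ({self.support_lo})"
            )
        if self.values is None:
            object.__setattr__(self, "values", tuple(self.centers))
        else:
            vals = tuple(float(v) for v in self.values)
            if len(vals) != self.k:
                raise ValueError(f"expected {self.k} representative values, got {len(vals)}")
            if any(not (self.support_lo <= v <= self.support_hi) for v in vals):
                raise ValueError("representative values must lie within the support")
            object.__setattr__(self, "values", vals)

    @property
    def edges(self) -> np.ndarray:
        """K+1 ascending bin edges (uniform width)."""
        return np.linspace(self.support_lo, self.support_hi, self.k + 1)

    @property
    def width(self) -> float:
        return (self.support_hi - self.support_lo) / self.k

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def bin_of(self, values: Sequence[float] | np.ndarray) -> np.ndarray:
        """Map numeric values to 0-based bin indices.

        Bins are half-open ``[e_i, e_{i+1})``; a value exactly equal to
        ``support_hi`` falls in the last bin.  Out-of-range values raise
        ``ValueError`` reporting the first offending index and value.
        """
        v = np.asarray(values, dtype=float)
        bad = (v < self.support_lo) | (v > self.support_hi)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"value {v.flat[i]!r} at position {i} is outside the support "
                f"[{self.support_lo}, {self.support_hi}]"
            )
        idx = np.floor((v - self.support_lo) / self.width).astype(int)
        return np.minimum(idx, self.k - 1)

    def same_binning(self, other: "BinGrid") -> bool:
        return (
            self.k == other.k
            and math.isclose(self.support_lo, other.support_lo, abs_tol=1e-12)
            and math.isclose(self.support_hi, other.support_hi, abs_tol=1e-12)
        )


def default_grid(k: int = 9, lo: float = 0.0, overhang: float = 0.001) -> BinGrid:
    """The benchmark grid: ``k`` bins over ``[lo, lo+k+overhang]``, integer outcomes.

    Outcome ``j`` (j = 1..k) is the representative value of bin ``j-1``; with
    the small overhang every outcome is strictly inside the support.
    """
    return BinGrid(k, lo, lo + k + overhang, values=tuple(float(j) for j in range(1, k + 1)))


@dataclasses.dataclass(frozen=True)
class BinnedDistribution:
    """Probability vector over the bins of a grid (sums to 1, entries in [0, 1])."""

    grid: BinGrid
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.array(self.probs, dtype=float)
        if p.shape != (self.grid.k,):
            raise ValueError(f"expected {self.grid.k} probabilities, got shape {p.shape}")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
        p.flags.writeable = False
        object.__setattr__(self, "probs", p)

    @property
    def k(self) -> int:
        return self.grid.k


@dataclasses.dataclass(frozen=True)
class SampleCounts:
    """Non-negative integer observation counts per bin; ``n`` is their total."""

    grid: BinGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (self.grid.k,):
            raise ValueError(f"expected {self.grid.k} counts, got shape {c.shape}")
        if not np.issubdtype(c.dtype, np.integer):
            ci = np.asarray(c, dtype=float)
            if np.any(ci != np.floor(ci)):
                raise ValueError("counts must be integers")
            c = ci.astype(np.int64)
        else:
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        c.flags.writeable = False
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return self.grid.k


def _clamp_normalize(p: np.ndarray) -> np.ndarray:
    """Clamp sub-`ZERO_CLAMP` entries to exact zero and renormalize."""
    p = np.where(p < ZERO_CLAMP, 0.0, p)
    return p / p.sum()


def _gaussian_bins(grid: BinGrid, mean: float, sigma: float) -> np.ndarray:
    from scipy.special import ndtr

    z = (grid.edges - mean) / sigma
    cdf = ndtr(z)
    return cdf[1:] - cdf[:-1]


def make_test_distribution(name: str, grid: BinGrid | None = None) -> BinnedDistribution:
    """Build one of the named benchmark distributions.

    The six 9-bin shapes (``uniform``, ``dirac``, ``normal_narrow``,
    ``normal_wide``, ``bimodal``, ``irregular``) require a 9-bin grid;
    ``demo6`` — the halving-rule demonstration distribution over outcomes
    {1..6} with p(1) ≈ 0.51 and each further probability half the previous —
    requires 6 bins.  If ``grid`` is omitted, the matching default grid is
    used.

    Gaussian shapes are discretized by CDF differences over the bin edges and
    renormalized; probabilities below 1e-12 are clamped to exact zeros so that
    "true-zero bin" is well defined.
    """
    if name not in TEST_DISTRIBUTIONS:
        raise ValueError(f"unknown test distribution {name!r}; choose from {TEST_DISTRIBUTIONS}")
    want_k = 6 if name == "demo6" else 9
    if grid is None:
        grid = default_grid(want_k)
    if grid.k != want_k:
        raise ValueError(f"distribution {name!r} requires a {want_k}-bin grid, got {grid.k}")

    w = grid.width
    mid = 0.5 * (grid.support_lo + grid.support_hi)
    centers = grid.centers

    if name == "uniform":
        p = np.full(grid.k, 1.0 / grid.k)
    elif name == "dirac":
        p = np.zeros(grid.k)
        p[grid.k // 2] = 1.0
    elif name == "normal_narrow":
        p = _gaussian_bins(grid, mid, 0.5 * w)
    elif name == "normal_wide":
        p = _gaussian_bins(grid, mid, 1.5 * w)
    elif name == "bimodal":
        p = 0.5 * _gaussian_bins(grid, centers[2], 0.5 * w) + 0.5 * _gaussian_bins(
            grid, centers[7], 0.5 * w
        )
    elif name == "irregular":
        p = np.array(IRREGULAR_PROBS)
    else:  # demo6: normalized geometric halving series 32/63, 16/63, ..., 1/63
        p = 0.5 ** np.arange(grid.k, dtype=float)
    return BinnedDistribution(grid, _clamp_normalize(p))


def sample_counts(
    dist: BinnedDistribution,
    n: int,
    rng: int | np.random.Generator | None = None,
) -> SampleCounts:
    """Draw an i.i.d. sample of size ``n`` (with replacement) as bin counts.

    Counts follow a multinomial law with the distribution's probabilities.
    The same seed yields the same counts.
    """
    if n < 0:
        raise ValueError(f"sample size must be non-negative, got {n}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return SampleCounts(dist.grid, gen.multinomial(int(n), dist.probs))


def histogram_from_values(values: Sequence[float] | np.ndarray, grid: BinGrid) -> SampleCounts:
    """Bin raw numeric observations into counts using the grid's half-open bins."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return SampleCounts(grid, np.zeros(grid.k, dtype=np.int64))
    idx = grid.bin_of(v)
    return SampleCounts(grid, np.bincount(idx, minlength=grid.k).astype(np.int64))
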