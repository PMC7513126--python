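"""Exact (Clopper-Pearson) confidence intervals for a binomial proportion.

Whether a single i.i.d. draw lands in a given histogram bin is a Bernoulli
trial, so the number of observations ``x`` in a bin out of ``n`` draws is
binomial with the bin-occupation probability as success probability.  The
Clopper-Pearson interval inverts the exact binomial tails and is therefore
valid (if conservative) at any sample size — including the small samples where
empty bins are most likely.

The production path uses the classical binomial-Beta duality: the lower bound
is the α/2 quantile of Beta(x, n-x+1) (0 when x = 0) and the upper bound the
1-α/2 quantile of Beta(x+1, n-x) (1 when x = n).  An independent brute-force
oracle (:func:`cp_interval_oracle`) solves the defining tail equations by
bisection over binomial-coefficient sums and is used to cross-check the Beta
route in the test suite.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as _beta

__all__ = ["ConfidenceInterval", "cp_interval", "cp_interval_oracle", "cp_bounds"]


@dataclasses.dataclass(frozen=True)
class ConfidenceInterval:
    """A ``[lower, upper]`` interval for one bin-occupation probability."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(f"invalid bounds [{self.lower}, {self.upper}]")
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"confidence level must be in (0, 1), got {self.level}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _validate(x: int, n: int, level: float) -> None:
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"observation count x={x} must satisfy 0 <= x <= n={n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")


def cp_bounds(x: np.ndarray, n: int, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Clopper-Pearson bounds for counts ``x`` out of ``n`` draws."""
    x = np.asarray(x, dtype=np.int64)
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    a2 = 0.5 * (1.0 - level)
    lower = np.zeros(x.shape, dtype=float)
    upper = np.ones(x.shape, dtype=float)
    pos = x > 0
    if np.any(pos):
        lower[pos] = _beta.ppf(a2, x[pos], n - x[pos] + 1)
    below = x < n
    if np.any(below):
        upper[below] = _beta.ppf(1.0 - a2, x[below] + 1, n - x[below])
    return lower, upper


def cp_interval(x: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Exact Clopper-Pearson interval for ``x`` successes in ``n`` trials.

    Computed through Beta-distribution quantiles; always contains ``x/n`` and
    has strictly positive width for any level in (0, 1).
    """
    _validate(x, n, level)
    lower, upper = cp_bounds(np.array([x]), n, level)
    return ConfidenceInterval(float(lower[0]), float(upper[0]), level)


def _tail_ge(x: int, n: int, p: float, combs: np.ndarray, i: np.ndarray) -> float:
    # P[Bin(n, p) >= x], summed directly from binomial coefficients
    return float(np.sum(combs * p**i * (1.0 - p) ** (n - i)))


def cp_interval_oracle(x: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Brute-force Clopper-Pearson bounds via bisection on the binomial tails.

    The lower bound solves ``P[Bin(n, p) >= x] = α/2`` (0 when x = 0) and the
    upper bound ``P[Bin(n, p) <= x] = α/2`` (1 when x = n), with tail
    probabilities summed term by term from binomial coefficients.  Intended
    for modest ``n`` (≤ a few hundred); used as an independent check of
    :func:`cp_interval`.
    """
    _validate(x, n, level)
    a2 = 0.5 * (1.0 - level)
    eps = 1e-300

    if x == 0:
        lower = 0.0
    else:
        i = np.arange(x, n + 1)
        combs = np.array([math.comb(n, int(j)) for j in i], dtype=float)
        lower = brentq(
            lambda p: _tail_ge(x, n, p, combs, i) - a2, eps, 1.0 - eps, xtol=1e-12
        )
    if x == n:
        upper = 1.0
    else:
        # P[Bin <= x] = P[Bin(n, 1-p) >= n-x]
        i = np.arange(0, x + 1)
        combs = np.array([math.comb(n, int(j)) for j in i], dtype=float)
        upper = brentq(
            lambda p: float(np.sum(combs * p**i * (1.0 - p) ** (n - i))) - a2,
            eps,
            1.0 - eps,
            xtol=1e-12,
        )
    return ConfidenceInterval(float(lower), float(upper), level)
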