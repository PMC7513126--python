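"""Kullback-Leibler divergence between binned distributions, in bits.

``kl_divergence(p, q)`` computes ``Σ_k p_k · log2(p_k / q_k)`` with the usual
conventions: bins with ``p_k = 0`` contribute nothing regardless of ``q_k``,
and any bin with ``p_k > 0`` but ``q_k = 0`` makes the divergence positive
infinity.  The direction is fixed by use: the full (true) distribution is the
reference ``p``, the sample-based estimate is ``q``.
"""

from __future__ import annotations

import math

import numpy as np

from .distributions import BinnedDistribution

__all__ = ["kl_divergence"]


def kl_divergence(p: BinnedDistribution, q: BinnedDistribution) -> float:
    """KL divergence ``D_KL(p || q)`` in bits; ``inf`` if q is zero where p is not."""
    if not p.grid.same_binning(q.grid):
        raise ValueError(
            f"distributions use different binnings ({p.grid} vs {q.grid})"
        )
    pp = p.probs
    qq = q.probs
    support = pp > 0.0
    if np.any(qq[support] == 0.0):
        return math.inf
    ps = pp[support]
    # log difference form avoids overflow when q carries subnormal mass
    return float(np.sum(ps * (np.log2(ps) - np.log2(qq[support]))))
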