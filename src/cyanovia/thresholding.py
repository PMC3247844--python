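"""Maximum-entropy (Kapur–Sahoo–Wong) automatic histogram thresholding.

The threshold ``t`` splits an 8-bit histogram into background (intensities
``<= t``) and foreground (``> t``) and is chosen to maximise the sum of the
Shannon entropies of the two class-conditional intensity distributions:

    H_b(t) = -sum_{i<=t} (p_i / P_t) ln(p_i / P_t)
    H_f(t) = -sum_{i>t} (p_i / (1 - P_t)) ln(p_i / (1 - P_t))

with ``p_i`` the normalised bin probabilities and ``P_t = sum_{i<=t} p_i``.
Natural logarithms are used; the argmax is base-invariant.  Empty bins
contribute zero (the limit x ln x -> 0), candidates that leave either class
empty are skipped, and ties are broken towards the smallest ``t``.

:func:`max_entropy_threshold` is the production (cumulative-sum) path;
:func:`max_entropy_threshold_oracle` re-evaluates the criterion literally at
every candidate and exists purely as an independent cross-check in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import CyanoviaError

N_LEVELS = 256


class DegenerateHistogramError(CyanoviaError):
    """Histogram has fewer than two occupied bins: no split is possible."""


@dataclass(frozen=True)
class ChannelHistogram:
    """256-bin intensity histogram of one channel."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValueError(f"counts must have shape (256,), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("histogram total must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_occupied(self) -> int:
        return int((self.counts > 0).sum())


def histogram(channel: np.ndarray) -> ChannelHistogram:
    """Tally a 2-D intensity grid into a :class:`ChannelHistogram`."""
    arr = np.asarray(channel)
    if arr.size == 0:
        raise ValueError("cannot histogram an empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    counts = np.bincount(arr.astype(np.int64).ravel(), minlength=N_LEVELS)
    return ChannelHistogram(counts=counts)


def max_entropy_threshold(h: ChannelHistogram) -> int:
    """Return the entropy-maximising threshold ``t`` in ``[0, 254]``.

    Pixels with intensity ``> t`` are foreground.  Raises
    :class:`DegenerateHistogramError` when fewer than two bins are occupied.
    """
    if h.n_occupied < 2:
        raise DegenerateHistogramError(
            f"need >= 2 occupied bins, got {h.n_occupied}"
        )
    p = h.counts / h.total
    cum_p = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    cum_plogp = np.cumsum(plogp)
    total_plogp = cum_plogp[-1]

    cum_counts = np.cumsum(h.counts)
    best_t = -1
    best_h = -math.inf
    for t in range(N_LEVELS - 1):
        n_b = cum_counts[t]
        if n_b == 0 or n_b == h.total:
            continue  # one class empty: not a valid split
        p_b = cum_p[t]
        p_f = 1.0 - p_b
        h_b = -cum_plogp[t] / p_b + math.log(p_b)
        h_f = -(total_plogp - cum_plogp[t]) / p_f + math.log(p_f)
        crit = h_b + h_f
        if crit > best_h:
            best_h = crit
            best_t = t
    return best_t


def max_entropy_threshold_oracle(h: ChannelHistogram) -> int:
    """Brute-force reference: recompute both entropies from scratch per ``t``.

    Kept deliberately naive (O(levels^2), plain Python) and independent of
    :func:`max_entropy_threshold`; the two must agree on every valid input.
    """
    if h.n_occupied < 2:
        raise DegenerateHistogramError(
            f"need >= 2 occupied bins, got {h.n_occupied}"
        )
    total = h.total
    p = [c / total for c in h.counts.tolist()]
    best_t = -1
    best_h = -math.inf
    for t in range(N_LEVELS - 1):
        p_b = sum(p[: t + 1])
        p_f = sum(p[t + 1 :])
        if p_b <= 0 or p_f <= 0:
            continue
        h_b = 0.0
        for i in range(t + 1):
            if p[i] > 0:
                q = p[i] / p_b
                h_b -= q * math.log(q)
        h_f = 0.0
        for i in range(t + 1, N_LEVELS):
            if p[i] > 0:
                q = p[i] / p_f
                h_f -= q * math.log(q)
        crit = h_b + h_f
        if crit > best_h:
            best_h = crit
            best_t = t
    return best_t


def binarize(channel: np.ndarray, t: int) -> np.ndarray:
    """Foreground mask: True where intensity strictly exceeds ``t``."""
    if not 0 <= t <= 254:
        raise ValueError(f"threshold must lie in [0, 254], got {t}")
    return np.asarray(channel) > t
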