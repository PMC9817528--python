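"""Temporal post-processing of classifier output.

Two stages, applied to the time-ordered probability stream of one ride:

1. exponential weight decay: ``z_0 = h_0``, ``z_t = (z_{t-1} + h_t) / 2`` —
   each refined vector halves the influence of the past at every step;
2. a centred sliding majority vote of width 7 over the hard labels
   ``g_t = argmax z_t``, with ties broken in favour of ``g_t`` itself.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .gaits import Gait


class ConfigError(ValueError):
    pass


def exp_decay(h: np.ndarray) -> np.ndarray:
    """Exponentially decayed probability stream.

    ``h`` is (T, 5) with simplex rows; returns ``z`` of the same shape with
    ``z_0 = h_0`` and ``z_t = (z_{t-1} + h_t)/2``. Rows remain on the
    simplex (convex combinations of simplex vectors).
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or len(h) == 0:
        raise ValueError("h must be a nonempty (T, k) array")
    z = np.empty_like(h)
    z[0] = h[0]
    for t in range(1, len(h)):
        z[t] = 0.5 * (z[t - 1] + h[t])
    return z


def argmax_gait(z: np.ndarray) -> Gait:
    """Hard label of one probability vector; ties go to the lowest gait code."""
    z = np.asarray(z, dtype=float)
    return Gait(int(np.argmax(z)))  # np.argmax returns the first (lowest) maximum


def hard_labels(z: np.ndarray) -> np.ndarray:
    """Vectorised argmax over rows, lowest-code tie-break."""
    return np.argmax(np.asarray(z, dtype=float), axis=1)


def majority_smooth(g: Sequence[int], width: int = 7) -> np.ndarray:
    """Centred sliding majority vote over a hard-label sequence.

    At each position the most common label in the window of ``width``
    neighbours wins; the window is truncated at the sequence edges; a tie
    for most-common keeps the centre label ``g_t``.
    """
    if width % 2 == 0:
        raise ConfigError("majority window width must be odd")
    g = np.asarray(g, dtype=np.int64)
    half = width // 2
    n = len(g)
    out = np.empty_like(g)
    for i in range(n):
        window = g[max(0, i - half) : min(n, i + half + 1)]
        counts = np.bincount(window)
        best = counts.max()
        winners = np.nonzero(counts == best)[0]
        out[i] = g[i] if g[i] in winners else winners[np.argmax(counts[winners])]
    return out


@dataclasses.dataclass
class ProbSeries:
    """One ride's probability stream with its smoothed and hard versions."""

    t: np.ndarray
    h: np.ndarray  # raw network outputs, (T, 5)
    z: np.ndarray  # exponentially decayed, (T, 5)
    g: np.ndarray  # argmax of z
    g_prime: np.ndarray  # after majority vote

    @classmethod
    def from_probs(
        cls, t: Sequence[float], h: np.ndarray, width: int = 7
    ) -> "ProbSeries":
        """Run the full post-processing chain on raw probabilities."""
        h = np.asarray(h, dtype=float)
        z = exp_decay(h)
        g = hard_labels(z)
        return cls(
            t=np.asarray(t, dtype=float),
            h=h,
            z=z,
            g=g,
            g_prime=majority_smooth(g, width),
        )
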