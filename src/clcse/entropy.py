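"""Shannon entropy of gray-level histograms and the left/right split decomposition.

A histogram is a length-256 vector of nonnegative counts over the 8-bit gray
levels.  Splitting it at a level ``l`` yields a left part (levels ``< l``) and a
right part (levels ``>= l``).  Writing ``S-`` and ``S+`` for the entropies of
the two parts, ``S`` for the entropy of their mixture and
``lambda = mu- / (mu- + mu+)`` for the left mass fraction, the entropy
difference

    S_delta = S+ - S = lambda * (S+ - S-) + lambda*log2(lambda)
                       + (1 - lambda)*log2(1 - lambda)

is large when the heavy side of the histogram is concentrated and the light
side is dispersed — the signature of a gradient image whose noise responses
have collapsed to zero while edge responses stay spread over the gray range.
Maximising ``S_delta`` over split levels (and, one level up, over the depth of
the multiscale product) is what drives the scale selection in this package.

All entropies are in bits (log base 2) and use the convention 0*log(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_LEVELS = 256


class DegenerateSplitError(ValueError):
    """Raised when one side of a histogram split carries no mass."""


def as_histogram(counts) -> np.ndarray:
    """Validate and return a 256-bin count vector as an int64 array."""
    h = np.asarray(counts, dtype=np.int64)
    if h.shape != (N_LEVELS,):
        raise ValueError(f"histogram must have {N_LEVELS} bins, got shape {h.shape}")
    if (h < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    return h


def shannon_entropy(counts) -> float:
    """Shannon entropy in bits of the probability view of a count vector.

    Empty and single-bin histograms have entropy 0.  Zero bins contribute
    nothing (the 0*log0 convention), so the result is bounded by
    ``log2(#nonzero bins)``.
    """
    h = np.asarray(counts, dtype=np.float64)
    total = h.sum()
    if total <= 0:
        return 0.0
    p = h[h > 0] / total
    return float(max(-(p * np.log2(p)).sum(), 0.0))  # max() guards against -0.0


def split_histogram(counts, l: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a histogram at gray level ``l`` into left ``[0, l)`` and right ``[l, 255]``.

    The split level itself belongs to the right part, matching the half-open
    band convention used for multi-level thresholding.
    """
    h = as_histogram(counts)
    if not 1 <= l <= N_LEVELS - 1:
        raise ValueError(f"split level must be in [1, 255], got {l}")
    left = np.zeros(N_LEVELS, dtype=np.int64)
    right = np.zeros(N_LEVELS, dtype=np.int64)
    left[:l] = h[:l]
    right[l:] = h[l:]
    return left, right


@dataclass(frozen=True)
class SplitEntropy:
    """Entropy bookkeeping for one histogram split.

    Attributes
    ----------
    l : split gray level (right part starts here).
    lam : left mass fraction mu- / (mu- + mu+), in (0, 1).
    s_minus, s_plus : entropies in bits of the left and right parts.
    s_total : entropy of the mixture of both parts.
    s_delta : S+ - S, the Shannon entropy difference.
    """

    l: int
    lam: float
    s_minus: float
    s_plus: float
    s_total: float
    s_delta: float

    def closed_form(self) -> float:
        """The equivalent closed form lam*(S+ - S-) + lam*log2(lam) + (1-lam)*log2(1-lam)."""
        lam = self.lam
        return (
            lam * (self.s_plus - self.s_minus)
            + lam * np.log2(lam)
            + (1.0 - lam) * np.log2(1.0 - lam)
        )


def entropy_difference(counts, l: int) -> SplitEntropy:
    """Compute the Shannon entropy difference S+ - S for a split at level ``l``.

    Raises
    ------
    DegenerateSplitError
        If either side of the split is empty; the part entropies are undefined
        there and callers scanning over ``l`` should skip such splits.
    """
    h = as_histogram(counts)
    left, right = split_histogram(h, l)
    mu_minus = int(left.sum())
    mu_plus = int(right.sum())
    if mu_minus == 0 or mu_plus == 0:
        raise DegenerateSplitError(f"split at l={l} leaves an empty side")
    lam = mu_minus / (mu_minus + mu_plus)
    s_minus = shannon_entropy(left)
    s_plus = shannon_entropy(right)
    s_total = shannon_entropy(h)
    return SplitEntropy(
        l=l,
        lam=lam,
        s_minus=s_minus,
        s_plus=s_plus,
        s_total=s_total,
        s_delta=s_plus - s_total,
    )


def best_split(counts) -> tuple[int, float]:
    """Return ``(l*, S_delta*)`` maximising the entropy difference over all splits.

    Degenerate splits (an empty side) are skipped.  Ties break toward the
    smallest ``l``.  A histogram with fewer than two nonzero bins admits no
    valid split and raises ``ValueError``.
    """
    h = as_histogram(counts)
    if int((h > 0).sum()) < 2:
        raise ValueError("no valid split: histogram has fewer than 2 nonzero bins")
    best_l = -1
    best_delta = -np.inf
    cum = np.cumsum(h)
    total = cum[-1]
    for l in range(1, N_LEVELS):
        mu_minus = cum[l - 1]
        if mu_minus == 0 or mu_minus == total:
            continue
        se = entropy_difference(h, l)
        if se.s_delta > best_delta:
            best_delta = se.s_delta
            best_l = l
    return best_l, float(best_delta)
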