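"""The contour-sampled Shannon entropy objective function (SEOF) and its maxima.

For each candidate threshold ``t`` the input image is binarized, the inner and
outer contours of the binary image are extracted, and the multiscale
multiplication image ``A*`` is sampled at the contour pixels.  The Shannon
entropy of the sampled histogram is the objective value at ``t``.  Contours
that fall on genuine object boundaries sample the dispersed high-gray tail of
``A*`` and score high; contours inside homogeneous regions sample the
concentrated near-zero mass and score low.  Local maxima of the curve are the
candidate thresholds from which the final subset is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import extract_contours, threshold_binary
from .entropy import shannon_entropy
from .multiscale import N_LEVELS, as_gray_image


def sample_histogram(a_star, mask) -> np.ndarray:
    """256-bin histogram of ``a_star`` values at mask-1 positions.

    An empty mask yields the empty histogram, whose entropy is 0 by the
    package-wide convention, keeping the objective total over its domain.
    """
    a = as_gray_image(a_star)
    m = np.asarray(mask)
    if m.shape != a.shape:
        raise ValueError(f"mask shape {m.shape} does not match image shape {a.shape}")
    return np.bincount(a[m.astype(bool)], minlength=N_LEVELS)


@dataclass(frozen=True)
class SeofCurve:
    """The entropy objective sampled at every admissible threshold.

    ``t_values`` runs over ``[min(f)+1, max(f)]`` so both classes of the
    binarization are always nonempty; ``entropy_values`` holds the matching
    contour-sampled entropies in bits.
    """

    t_values: np.ndarray
    entropy_values: np.ndarray

    def __post_init__(self):
        if len(self.t_values) != len(self.entropy_values):
            raise ValueError("t_values and entropy_values must have equal length")

    def value_at(self, t: int) -> float:
        idx = int(t) - int(self.t_values[0])
        if not 0 <= idx < len(self.t_values):
            raise ValueError(f"threshold {t} outside the curve domain")
        return float(self.entropy_values[idx])


def seof_curve(f, a_star) -> SeofCurve:
    """Evaluate the contour-sampled entropy objective over every threshold.

    Deterministic; raises ``ValueError`` for a constant image, which admits no
    threshold range.
    """
    img = as_gray_image(f)
    a = as_gray_image(a_star)
    if a.shape != img.shape:
        raise ValueError(f"image shapes differ: {img.shape} vs {a.shape}")
    lo, hi = int(img.min()), int(img.max())
    if lo == hi:
        raise ValueError("no threshold range: image is constant")
    a_flat = a.ravel()
    t_values = np.arange(lo + 1, hi + 1, dtype=np.int64)
    entropies = np.empty(len(t_values), dtype=np.float64)
    for j, t in enumerate(t_values):
        contour = extract_contours(threshold_binary(img, int(t)))
        hist = np.bincount(a_flat[contour.ravel().astype(bool)], minlength=N_LEVELS)
        entropies[j] = shannon_entropy(hist)
    return SeofCurve(t_values=t_values, entropy_values=entropies)


def local_maxima(curve: SeofCurve) -> np.ndarray:
    """Gray levels at the local maxima of the objective curve.

    A point qualifies when its value is >= both existing neighbors' values
    (endpoints compare against their single neighbor).  A maximal run of
    consecutive qualifying points with equal value — a plateau — collapses to
    its midpoint, taking the left of the two central points for even-length
    runs.  Returns an ascending array of unique candidate gray levels.
    """
    v = np.asarray(curve.entropy_values, dtype=np.float64)
    t = np.asarray(curve.t_values, dtype=np.int64)
    n = len(v)
    if n == 0:
        raise ValueError("empty curve")
    if n == 1:
        return t.copy()
    ge_left = np.empty(n, dtype=bool)
    ge_right = np.empty(n, dtype=bool)
    ge_left[0] = True
    ge_left[1:] = v[1:] >= v[:-1]
    ge_right[-1] = True
    ge_right[:-1] = v[:-1] >= v[1:]
    qualifies = ge_left & ge_right

    members: list[int] = []
    i = 0
    while i < n:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qualifies[j + 1] and v[j + 1] == v[i]:
            j += 1
        members.append(int(t[(i + j) // 2]))
        i = j + 1
    return np.asarray(members, dtype=np.int64)
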