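"""Independent straight-line reference implementations used as test oracles.

Everything here is written as directly as possible — explicit Python loops,
no shared code with the package — so that agreement between the two routes
is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def naive_entropy(counts) -> float:
    total = sum(int(c) for c in counts)
    if total == 0:
        return 0.0
    s = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            s -= p * math.log2(p)
    return s


def naive_split_entropy(counts, l):
    """Direct computation of (S-, S+, S, S_delta) for a split at level l."""
    left = [int(c) for c in counts[:l]]
    right = [int(c) for c in counts[l:]]
    mu_minus, mu_plus = sum(left), sum(right)
    if mu_minus == 0 or mu_plus == 0:
        raise ValueError("degenerate split")
    s_minus = naive_entropy(left)
    s_plus = naive_entropy(right)
    # total entropy via the explicit mixture weights
    total = mu_minus + mu_plus
    s = 0.0
    for c in left:
        if c > 0:
            o = (mu_minus / total) * (c / mu_minus)
            s -= o * math.log2(o)
    for c in right:
        if c > 0:
            o = (mu_plus / total) * (c / mu_plus)
            s -= o * math.log2(o)
    return s_minus, s_plus, s, s_plus - s


def closed_form_delta(lam, s_minus, s_plus) -> float:
    return (
        lam * (s_plus - s_minus)
        + lam * math.log2(lam)
        + (1 - lam) * math.log2(1 - lam)
    )


def naive_convolve_reflect(img, kernel):
    """Dense 2-D convolution with mirror-reflect borders, quadruple loop."""
    img = np.asarray(img, dtype=float)
    k = np.asarray(kernel, dtype=float)
    n, m = img.shape
    kh, kw = k.shape
    rh, rw = kh // 2, kw // 2

    def reflect(idx, size):
        # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
        while idx < 0 or idx >= size:
            if idx < 0:
                idx = -idx - 1
            if idx >= size:
                idx = 2 * size - idx - 1
        return idx

    out = np.zeros_like(img)
    for r in range(n):
        for c in range(m):
            acc = 0.0
            for dr in range(-rh, rh + 1):
                for dc in range(-rw, rw + 1):
                    # convolution flips the kernel
                    acc += k[rh - dr, rw - dc] * img[
                        reflect(r + dr, n), reflect(c + dc, m)
                    ]
            out[r, c] = acc
    return out


def naive_contours(b):
    """Inner+outer contour of a binary image by per-pixel 4-neighbor loops.

    Starts from an all-ones result; a pixel is cleared when, in whichever of
    the image or its complement it has value 1, all its in-image 4-neighbors
    also have value 1 (i.e. it is interior on its own side).
    """
    b = np.asarray(b).astype(int)
    n, m = b.shape
    out = np.ones((n, m), dtype=int)
    for r in range(n):
        for col in range(m):
            img = b if b[r, col] == 1 else 1 - b
            interior = True
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, col + dc
                if 0 <= rr < n and 0 <= cc < m and img[rr, cc] != 1:
                    interior = False
                    break
            if interior:
                out[r, col] = 0
    return out


def naive_band_masks(f, thresholds):
    """The n+1 half-open band indicators, by per-pixel comparison."""
    f = np.asarray(f)
    ts = list(thresholds)
    edges = [None] + ts + [None]
    bands = []
    for i in range(len(ts) + 1):
        lo, hi = edges[i], edges[i + 1]
        mask = np.ones(f.shape, dtype=int)
        if lo is not None:
            mask &= (f >= lo).astype(int)
        if hi is not None:
            mask &= (f < hi).astype(int)
        bands.append(mask)
    return bands


def naive_composite_objective(f, a_star, subset) -> float:
    """Straight-line recomputation of the composite contour entropy score."""
    a = np.asarray(a_star)
    contours = [naive_contours(b) for b in naive_band_masks(f, subset)]
    counts = [int(c.sum()) for c in contours]
    i_max = counts.index(max(counts))
    standalone = contours[i_max]
    fused = np.zeros_like(standalone)
    for j, c in enumerate(contours):
        if j != i_max:
            fused = fused | c
    def sampled_entropy(mask):
        vals = a[mask.astype(bool)]
        hist = [0] * 256
        for v in vals:
            hist[int(v)] += 1
        return naive_entropy(hist)
    s_f = sampled_entropy(fused)
    s_fc = sampled_entropy(1 - fused)
    s_m = sampled_entropy(standalone)
    s_mc = sampled_entropy(1 - standalone)
    if s_fc == 0.0 or s_mc == 0.0:
        return float("-inf")
    return s_f / s_fc + s_m / s_mc


def naive_mcc(cm) -> float:
    """Multi-class MCC from confusion counts, written term by term."""
    cm = np.asarray(cm, dtype=float)
    k = cm.shape[0]
    s = cm.sum()
    c = sum(cm[i, i] for i in range(k))
    t = [sum(cm[j, i] for i in range(k)) for j in range(k)]  # actual (row sums)
    p = [sum(cm[i, j] for i in range(k)) for j in range(k)]  # predicted (col sums)
    num = c * s - sum(p[i] * t[i] for i in range(k))
    d1 = s * s - sum(x * x for x in p)
    d2 = s * s - sum(x * x for x in t)
    if d1 <= 0 or d2 <= 0:
        return 0.0
    return num / math.sqrt(d1 * d2)
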