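"""Binary thresholding, inner/outer contour extraction and contour composition.

A binary image's inner contour consists of its 1-pixels that touch a 0-pixel
through the 4-neighborhood; the outer contour applies the same rule to the
complement.  Their union — the contour image — therefore marks every pixel
whose value differs from at least one 4-neighbor, on either side of the
boundary.  Band images built from an ascending threshold set tile the image,
so each band's contour is covered by the union of the others'; with a single
threshold the two band contours coincide.  That redundancy motivates the
partial composition used for threshold scoring: the largest contour is kept
standalone and only the remaining ones are fused.
"""

from __future__ import annotations

import numpy as np

from .multiscale import as_gray_image


def as_binary_mask(pixels) -> np.ndarray:
    m = np.asarray(pixels)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {m.shape}")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    return m.astype(np.uint8)


def threshold_binary(f, t: int) -> np.ndarray:
    """Binarize ``f`` at gray level ``t``: 1 where ``f < t``, else 0.

    The direction matches the first band of the multi-level convention
    (class 0 is ``f < t1``); contour extraction is complement-symmetric, so
    the choice does not affect any contour-derived quantity.
    """
    return (as_gray_image(f) < t).astype(np.uint8)


def extract_contours(b) -> np.ndarray:
    """Union of inner and outer contours of a binary image, 4-neighborhood rule.

    A pixel is non-contour when every in-image 4-neighbor shares its value
    (applied to the mask and to its complement; the two passes mark the same
    pixels, namely those with at least one differing 4-neighbor).  Border
    pixels consider only their existing neighbors, so a uniform image — and a
    uniform frame — yields no contour.
    """
    m = as_binary_mask(b).astype(bool)
    diff = np.zeros(m.shape, dtype=bool)
    diff[1:, :] |= m[1:, :] != m[:-1, :]
    diff[:-1, :] |= m[:-1, :] != m[1:, :]
    diff[:, 1:] |= m[:, 1:] != m[:, :-1]
    diff[:, :-1] |= m[:, :-1] != m[:, 1:]
    return diff.astype(np.uint8)


def band_images(f, thresholds) -> list[np.ndarray]:
    """Indicator images of the n+1 half-open bands cut by ascending thresholds.

    Band 0 is ``f < t1``, band c is ``t_c <= f < t_{c+1}``, band n is
    ``f >= t_n``; a pixel equal to a threshold joins the upper band.
    """
    img = as_gray_image(f)
    ts = _check_thresholds(img, thresholds)
    labels = np.searchsorted(ts, img, side="right")
    return [(labels == c).astype(np.uint8) for c in range(len(ts) + 1)]


def band_contours(f, thresholds) -> list[np.ndarray]:
    """Contour images of the n+1 bands cut by an ascending threshold set."""
    return [extract_contours(b) for b in band_images(f, thresholds)]


def compose_contours(contours) -> tuple[np.ndarray, np.ndarray]:
    """Split contour images into a fused union and the largest standalone member.

    The member with the most contour pixels (ties: lowest index) is returned
    standalone; the fused image is the pixel-wise union of all the others.
    Keeping the dominant contour out of the union limits the overlap any one
    boundary contributes twice.
    """
    masks = [as_binary_mask(c) for c in contours]
    if len(masks) < 2:
        raise ValueError("contour composition needs at least 2 contour images")
    counts = [int(m.sum()) for m in masks]
    i_max = int(np.argmax(counts))  # argmax takes the first of tied maxima
    standalone = masks[i_max]
    fused = np.zeros_like(standalone)
    for j, m in enumerate(masks):
        if j != i_max:
            fused |= m
    return fused, standalone


def complement_mask(m) -> np.ndarray:
    """0/1 complement over the full image domain."""
    return (1 - as_binary_mask(m)).astype(np.uint8)


def _check_thresholds(img: np.ndarray, thresholds) -> np.ndarray:
    ts = np.asarray(thresholds, dtype=np.int64)
    if ts.ndim != 1 or ts.size == 0:
        raise ValueError("thresholds must be a nonempty 1-D sequence")
    if (np.diff(ts) <= 0).any():
        raise ValueError(f"thresholds must be strictly ascending, got {ts.tolist()}")
    lo, hi = int(img.min()), int(img.max())
    if ts[0] <= lo or ts[-1] > hi:
        raise ValueError(
            f"thresholds must lie in ({lo}, {hi}] for this image, got {ts.tolist()}"
        )
    return ts
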