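"""Composite local-contour entropy objective and exhaustive threshold selection.

Given a candidate set ``P`` (local maxima of the SEOF curve) and a requested
threshold count ``n``, every n-subset of ``P`` is scored as follows: the n+1
band contour images are built, the one with the most contour pixels is kept
standalone (``c_max``) while the rest are fused into a union (``C``); the
multiscale multiplication image is sampled at ``C``, ``c_max`` and their
complements, and the score is

    S(H_C) / S(H_C')  +  S(H_cmax) / S(H_cmax')

— the entropy of each contour sample relative to the entropy of its
complement sample.  Thresholds whose bands trace real object boundaries put
high-entropy edge pixels into the numerator histograms and leave the
concentrated near-zero mass to the complements, so the true boundary subset
maximises the ratio sum.  The argmax subset is found by exhaustive
enumeration, which is exact and cheap because ``P`` is small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .contours import band_contours, compose_contours
from .entropy import shannon_entropy
from .multiscale import MultiscaleSelection, as_gray_image, select_multiscale_image
from .seof import SeofCurve, local_maxima, sample_histogram, seof_curve

logger = logging.getLogger(__name__)

INVALID_SCORE = -np.inf
MAX_SUBSETS = 10**6


def _ratio_score(a_star, fused, standalone) -> float:
    """Entropy-ratio score of a fused/standalone contour pair; -inf when a
    complement histogram is degenerate (entropy 0)."""
    s_fused = shannon_entropy(sample_histogram(a_star, fused))
    s_fused_c = shannon_entropy(sample_histogram(a_star, 1 - fused))
    s_max = shannon_entropy(sample_histogram(a_star, standalone))
    s_max_c = shannon_entropy(sample_histogram(a_star, 1 - standalone))
    if s_fused_c == 0.0 or s_max_c == 0.0:
        return INVALID_SCORE
    return s_fused / s_fused_c + s_max / s_max_c


def composite_objective(f, a_star, subset) -> float:
    """Composite local-contour entropy score of one ascending threshold subset.

    Returns ``-inf`` when either complement histogram has zero entropy (the
    ratio is undefined there and the subset is treated as invalid).
    """
    contours = band_contours(f, subset)
    fused, standalone = compose_contours(contours)
    return _ratio_score(as_gray_image(a_star), fused, standalone)


class _CachedEvaluator:
    """Scores subsets while caching per-band contour images.

    A band is identified by its (lower, upper) threshold pair with ``None``
    sentinels at the extremes, so bands shared between subsets are extracted
    once.  Scores are identical to ``composite_objective``.
    """

    def __init__(self, f, a_star):
        self.f = as_gray_image(f)
        self.a_star = as_gray_image(a_star)
        self._cache: dict[tuple[int | None, int | None], np.ndarray] = {}

    def _band_contour(self, lo: int | None, hi: int | None) -> np.ndarray:
        key = (lo, hi)
        mask = self._cache.get(key)
        if mask is None:
            from .contours import extract_contours

            band = np.ones(self.f.shape, dtype=bool)
            if lo is not None:
                band &= self.f >= lo
            if hi is not None:
                band &= self.f < hi
            mask = extract_contours(band.astype(np.uint8))
            self._cache[key] = mask
        return mask

    def score(self, subset: tuple[int, ...]) -> float:
        edges: list[int | None] = [None, *subset, None]
        contours = [
            self._band_contour(edges[c], edges[c + 1]) for c in range(len(subset) + 1)
        ]
        fused, standalone = compose_contours(contours)
        return _ratio_score(self.a_star, fused, standalone)


@dataclass(frozen=True)
class ThresholdResult:
    """Full outcome of a multi-level thresholding run.

    Attributes
    ----------
    thresholds : the n selected gray levels, ascending.
    objective : composite contour-entropy score of the selected subset
        (``-inf`` only when the fallback path was taken).
    k_star, l_star : multiscale product depth and histogram split level that
        maximised the Shannon entropy difference.
    candidates : the full candidate set ``P``.
    curve : the SEOF curve the candidates came from.
    labels : label map of ``f`` under the selected thresholds (classes
        0..n, ascending in gray).
    a_star : the normalized multiscale multiplication image the contour
        histograms were sampled from.
    """

    thresholds: tuple[int, ...]
    objective: float
    k_star: int
    l_star: int
    candidates: np.ndarray
    curve: SeofCurve
    labels: np.ndarray
    a_star: np.ndarray

    def to_report(self) -> dict:
        """JSON-serializable summary (thresholds, scale choice, score, candidates)."""
        return {
            "thresholds": [int(t) for t in self.thresholds],
            "k_star": int(self.k_star),
            "l_star": int(self.l_star),
            "objective": float(self.objective),
            "candidates": [int(c) for c in self.candidates],
        }


def select_thresholds(
    f, a_star, candidates, n: int, curve: SeofCurve | None = None
) -> tuple[tuple[int, ...], float]:
    """Exhaustively pick the n-subset of the candidate set maximising the score.

    Ties break toward the lexicographically smallest threshold tuple.  If
    every subset is invalid (zero-entropy complements throughout) and a curve
    is supplied, falls back to the n candidates with the highest SEOF values;
    without a curve the fallback is unavailable and a ``ValueError`` is
    raised.  Enumeration aborts when the subset count exceeds ``10**6``.
    """
    p = np.unique(np.asarray(candidates, dtype=np.int64))
    if n < 1:
        raise ValueError(f"threshold count must be >= 1, got {n}")
    if len(p) < n:
        raise ValueError(
            f"insufficient candidates: need {n} thresholds but the candidate "
            f"set has only {len(p)} members (achievable maximum: {len(p)})"
        )
    n_subsets = comb(len(p), n)
    if n_subsets > MAX_SUBSETS:
        raise ValueError(
            f"subset enumeration too large: C({len(p)}, {n}) = {n_subsets} "
            f"exceeds {MAX_SUBSETS}"
        )
    evaluator = _CachedEvaluator(f, a_star)
    best_subset: tuple[int, ...] | None = None
    best_score = INVALID_SCORE
    for subset in combinations(p.tolist(), n):
        score = evaluator.score(subset)
        if score > best_score:
            best_score = score
            best_subset = subset
    if best_subset is None:
        if curve is None:
            raise ValueError("all candidate subsets are invalid and no curve "
                             "was supplied for the fallback")
        logger.warning(
            "all %d candidate subsets scored invalid; falling back to the %d "
            "candidates with highest SEOF values", n_subsets, n,
        )
        seof_vals = np.array([curve.value_at(int(t)) for t in p])
        order = np.argsort(-seof_vals, kind="stable")[:n]
        best_subset = tuple(sorted(int(p[i]) for i in order))
        best_score = INVALID_SCORE
    return best_subset, float(best_score)


def apply_thresholds(f, thresholds) -> np.ndarray:
    """Label map of ``f`` under ascending thresholds: class 0 is ``f < t1``,
    class c is ``t_c <= f < t_{c+1}``, class n is ``f >= t_n``."""
    img = as_gray_image(f)
    ts = np.asarray(thresholds, dtype=np.int64)
    if ts.ndim != 1 or ts.size == 0:
        raise ValueError("thresholds must be a nonempty 1-D sequence")
    if (np.diff(ts) <= 0).any():
        raise ValueError(f"thresholds must be strictly ascending, got {ts.tolist()}")
    return np.searchsorted(ts, img, side="right").astype(np.int64)


def clcse(f, n: int, k_max: int = 5) -> ThresholdResult:
    """Run the full pipeline: scale selection, SEOF curve, candidate extraction,
    exhaustive subset selection and labeling.  Deterministic given its inputs.
    """
    img = as_gray_image(f)
    if n < 1:
        raise ValueError(f"threshold count must be >= 1, got {n}")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValueError as e:
            raise ValueError(f"[{name}] {e}") from e

    ms: MultiscaleSelection = stage("multiscale", select_multiscale_image, img, k_max)
    curve = stage("seof", seof_curve, img, ms.a_star)
    candidates = stage("candidates", local_maxima, curve)
    thresholds, objective = stage(
        "selection", select_thresholds, img, ms.a_star, candidates, n, curve
    )
    labels = stage("labeling", apply_thresholds, img, thresholds)
    return ThresholdResult(
        thresholds=thresholds,
        objective=objective,
        k_star=ms.k_star,
        l_star=ms.l_star,
        candidates=candidates,
        curve=curve,
        labels=labels,
        a_star=ms.a_star,
    )
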