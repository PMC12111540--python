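"""Multi-class Matthews correlation coefficient for label-map agreement.

With confusion counts ``C[i, j]`` (rows true, columns predicted), class totals
``t_k = sum_i C[i, k]`` (actual) and ``p_k = sum_i C[k, i]`` (predicted),
correct count ``c = trace(C)`` and sample count ``s``, the multi-class MCC is

    MCC = (c*s - sum_k p_k t_k)
          / sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

It equals 1 only when every class is predicted perfectly, which makes it a
stricter segmentation score than per-pixel accuracy under the severe class
imbalance typical of thresholding benchmarks.  A vanishing denominator factor
(all mass in one predicted or one true class) yields MCC = 0.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def confusion_matrix(truth, pred, n_classes: int | None = None) -> np.ndarray:
    """K x K confusion counts; entry (i, j) counts pixels truly i predicted j.

    Both maps must share a shape; ``n_classes`` defaults to one more than the
    largest label present in either map.
    """
    t = np.asarray(truth, dtype=np.int64)
    p = np.asarray(pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label map shapes differ: {t.shape} vs {p.shape}")
    if t.min() < 0 or p.min() < 0:
        raise ValueError("labels must be nonnegative")
    k = int(max(t.max(), p.max())) + 1 if n_classes is None else int(n_classes)
    if max(int(t.max()), int(p.max())) >= k:
        raise ValueError(f"labels exceed the declared class count {k}")
    idx = t.ravel() * k + p.ravel()
    return np.bincount(idx, minlength=k * k).reshape(k, k)


def mcc_multiclass(cm) -> float:
    """Multi-class MCC of a confusion matrix; 0 when a denominator factor is 0."""
    c_mat = np.asarray(cm, dtype=np.float64)
    if c_mat.ndim != 2 or c_mat.shape[0] != c_mat.shape[1] or c_mat.size == 0:
        raise ValueError(f"confusion matrix must be square and nonempty, got {c_mat.shape}")
    s = c_mat.sum()
    if s <= 0:
        raise ValueError("confusion matrix is empty")
    c = np.trace(c_mat)
    t_k = c_mat.sum(axis=1)  # actual occurrences (rows are truth)
    p_k = c_mat.sum(axis=0)  # predicted occurrences
    num = c * s - (p_k * t_k).sum()
    d1 = s**2 - (p_k**2).sum()
    d2 = s**2 - (t_k**2).sum()
    if d1 <= 0 or d2 <= 0:
        return 0.0
    return float(num / np.sqrt(d1 * d2))


def match_labels(f, truth, pred, policy: str = "intensity") -> np.ndarray:
    """Relabel ``pred`` so its classes correspond to the truth's.

    ``"intensity"`` (default) orders both label sets by the ascending mean
    gray level of their regions in ``f`` and matches them rank-to-rank — the
    natural correspondence for threshold bands, and the identity whenever
    both sides already label classes in ascending intensity.  ``"best"``
    instead maximises the confusion-matrix trace over one-to-one assignments.
    Both policies require equal class counts.
    """
    t = np.asarray(truth, dtype=np.int64)
    p = np.asarray(pred, dtype=np.int64)
    t_classes = np.unique(t)
    p_classes = np.unique(p)
    if len(t_classes) != len(p_classes):
        raise ValueError(
            f"class counts differ: truth has {len(t_classes)}, "
            f"prediction has {len(p_classes)}"
        )
    if policy == "intensity":
        img = np.asarray(f, dtype=np.float64)
        t_order = t_classes[np.argsort([img[t == c].mean() for c in t_classes])]
        p_order = p_classes[np.argsort([img[p == c].mean() for c in p_classes])]
        mapping = dict(zip(p_order.tolist(), t_order.tolist()))
    elif policy == "best":
        k = int(max(t.max(), p.max())) + 1
        cm = confusion_matrix(t, p, n_classes=k)
        rows, cols = linear_sum_assignment(cm, maximize=True)
        mapping = {int(c): int(r) for r, c in zip(rows, cols)}
    else:
        raise ValueError(f"unknown matching policy {policy!r}")
    out = np.empty_like(p)
    for old, new in mapping.items():
        out[p == old] = new
    return out


def mcc_score(truth, pred, f=None, policy: str | None = None) -> float:
    """Convenience: confusion matrix + multi-class MCC, with optional matching.

    When ``policy`` is given, ``pred`` is first aligned to ``truth`` via
    ``match_labels`` (which needs ``f`` for the intensity policy).
    """
    if policy is not None:
        pred = match_labels(f, truth, pred, policy=policy)
    return mcc_multiclass(confusion_matrix(truth, pred))
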