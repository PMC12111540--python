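"""Composite contour-entropy objective, subset search and the full pipeline."""

from itertools import combinations

import numpy as np
import pytest

from clcse.selection import (
    apply_thresholds,
    clcse,
    composite_objective,
    select_thresholds,
)
from clcse.seof import local_maxima, seof_curve
from clcse.multiscale import select_multiscale_image
from clcse.synthetic import generate_scene, multi_target_scene, preset_suite

from oracles import naive_composite_objective


def test_composite_matches_straight_line_oracle(random_small_images, rng):
    for f in random_small_images[:6]:
        lo, hi = int(f.min()), int(f.max())
        if hi - lo < 4:
            continue
        a = rng.integers(0, 256, size=f.shape)
        for _ in range(3):
            n = int(rng.integers(1, 4))
            subset = np.unique(rng.integers(lo + 1, hi + 1, size=n)).tolist()
            got = composite_objective(f, a, subset)
            want = naive_composite_objective(f, a, subset)
            if np.isinf(want):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(want, rel=1e-9)


def test_zero_denominator_marks_subset_invalid():
    f = np.array([[0, 50], [100, 200]])
    a_const = np.full((2, 2), 7)  # every sample has a single gray -> S' = 0
    assert composite_objective(f, a_const, [60]) == -np.inf


def test_two_level_image_true_gap_candidate_wins(rng):
    f = np.where(rng.random((16, 16)) < 0.4, 50, 180)
    sel = select_multiscale_image(f, k_max=2)
    curve = seof_curve(f, sel.a_star)
    candidates = local_maxima(curve)
    in_gap = [t for t in candidates if 50 < t <= 180]
    assert in_gap
    scores = {int(t): composite_objective(f, sel.a_star, [int(t)])
              for t in candidates}
    best = max(scores, key=scores.get)
    assert 50 < best <= 180


def test_select_matches_exhaustive_oracle(rng):
    f = rng.integers(0, 200, size=(12, 12))
    a = rng.integers(0, 256, size=(12, 12))
    p = [15, 60, 110, 150, 190]
    p = [t for t in p if f.min() < t <= f.max()]
    n = 2
    chosen, score = select_thresholds(f, a, p, n)
    best = (-np.inf, None)
    for subset in combinations(p, n):
        s = composite_objective(f, a, list(subset))
        if s > best[0]:
            best = (s, subset)
    assert chosen == best[1]
    assert score == pytest.approx(best[0], rel=1e-12)


def test_select_returns_whole_set_when_sizes_match(rng):
    f = np.zeros((10, 10), dtype=int)
    f[:, 4:] = 100
    f[6:, :] = 180
    a = rng.integers(0, 256, size=(10, 10))
    p = [50, 120]
    chosen, _ = select_thresholds(f, a, p, 2)
    assert chosen == (50, 120)


def test_select_reports_insufficient_candidates():
    f = np.arange(100).reshape(10, 10) % 200
    a = np.zeros((10, 10), dtype=int)
    with pytest.raises(ValueError, match="only 2"):
        select_thresholds(f, a, [10, 20], 3)


def test_objective_invariant_to_candidate_order(rng):
    f = rng.integers(0, 200, size=(10, 10))
    a = rng.integers(0, 256, size=(10, 10))
    p = [30, 80, 150]
    r1 = select_thresholds(f, a, p, 2)
    r2 = select_thresholds(f, a, list(reversed(p)), 2)
    assert r1 == r2


def test_apply_thresholds_bands():
    f = np.array([[10, 100, 200]])
    np.testing.assert_array_equal(apply_thresholds(f, [50, 150]), [[0, 1, 2]])
    # a pixel equal to a threshold joins the upper band
    np.testing.assert_array_equal(apply_thresholds(np.array([[50]]), [50]), [[1]])


def test_apply_thresholds_label_count(rng):
    f = rng.integers(0, 256, size=(9, 9))
    labels = apply_thresholds(f, [64, 128, 192])
    assert labels.max() <= 3 and labels.min() >= 0


def test_apply_thresholds_validates_order():
    with pytest.raises(ValueError):
        apply_thresholds(np.array([[1, 2]]), [100, 100])


def test_pipeline_is_deterministic():
    img, _ = generate_scene(multi_target_scene(2, seed=42))
    r1 = clcse(img, n=2)
    r2 = clcse(img, n=2)
    assert r1.thresholds == r2.thresholds
    assert r1.objective == r2.objective
    assert (r1.k_star, r1.l_star) == (r2.k_star, r2.l_star)
    np.testing.assert_array_equal(r1.labels, r2.labels)
    np.testing.assert_array_equal(r1.candidates, r2.candidates)
    np.testing.assert_array_equal(r1.curve.entropy_values, r2.curve.entropy_values)


def test_pipeline_recovers_thresholds_inside_every_gap():
    """On a clean scene with well-separated levels every selected threshold
    falls strictly inside a distinct inter-level gap."""
    spec = dict(preset_suite())["targets-3"]
    img, _ = generate_scene(spec)
    levels = sorted([spec.background] + [r.gray for r in spec.regions])
    result = clcse(img, n=3)
    gaps = list(zip(levels[:-1], levels[1:]))
    hit = []
    for t in result.thresholds:
        matches = [i for i, (lo, hi) in enumerate(gaps) if lo < t <= hi]
        assert matches, f"threshold {t} outside every gap {gaps}"
        hit.append(matches[0])
    assert len(set(hit)) == len(result.thresholds)


def test_pipeline_rejects_constant_image():
    with pytest.raises(ValueError, match=r"\[multiscale\]"):
        clcse(np.full((8, 8), 5), n=1)


def test_pipeline_threshold_subset_of_candidates():
    img, _ = generate_scene(multi_target_scene(2, seed=7))
    res = clcse(img, n=2)
    assert set(res.thresholds) <= set(res.candidates.tolist())
    assert res.objective == pytest.approx(
        composite_objective(img, res.a_star, list(res.thresholds)), rel=1e-12
    )
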