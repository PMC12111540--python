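"""Histogram entropy, split machinery and the entropy-difference identities."""

import numpy as np
import pytest

from clcse.entropy import (
    DegenerateSplitError,
    best_split,
    entropy_difference,
    shannon_entropy,
    split_histogram,
)

from oracles import closed_form_delta, naive_split_entropy


def _hist(pairs):
    h = np.zeros(256, dtype=np.int64)
    for level, count in pairs:
        h[level] = count
    return h


@pytest.mark.parametrize(
    "counts, expected",
    [
        (np.full(256, 7), 8.0),                  # uniform over all bins
        (_hist([(13, 999)]), 0.0),               # all mass in one bin
        (_hist([(10, 5), (200, 5)]), 1.0),       # fair coin
        (np.zeros(256, dtype=int), 0.0),         # empty histogram
    ],
)
def test_entropy_known_values(counts, expected):
    assert shannon_entropy(counts) == pytest.approx(expected, abs=1e-12)


def test_entropy_bounded_by_log_nonzero_bins(random_histograms):
    for h in random_histograms:
        s = shannon_entropy(h)
        assert 0.0 <= s <= np.log2((h > 0).sum()) + 1e-12


def test_split_partitions_levels():
    h = _hist([(10, 3), (200, 4)])
    left, right = split_histogram(h, 100)
    assert left[10] == 3 and left.sum() == 3
    assert right[200] == 4 and right.sum() == 4


def test_split_boundary_level_belongs_to_right():
    h = _hist([(254, 2), (255, 5)])
    left, right = split_histogram(h, 255)
    assert right.sum() == 5 and right[255] == 5
    assert left[254] == 2


def test_split_conserves_total(random_histograms):
    for h in random_histograms[:10]:
        for l in range(1, 256):
            left, right = split_histogram(h, l)
            assert left.sum() + right.sum() == h.sum()


@pytest.mark.parametrize("l", [0, 256, -3])
def test_split_rejects_out_of_range(l):
    with pytest.raises(ValueError):
        split_histogram(_hist([(1, 1), (2, 1)]), l)


def test_equal_disjoint_halves_give_delta_minus_one():
    # lambda = 1/2 and S+ = S-, so only the -1 bit mixing term remains
    h = _hist([(10, 4), (20, 4), (200, 4), (210, 4)])
    se = entropy_difference(h, 100)
    assert se.s_delta == pytest.approx(-1.0, abs=1e-12)


def test_extreme_imbalance_delta():
    # S+ = S- = 0; delta reduces to the binary mixing entropy of 255:1
    h = _hist([(0, 255), (255, 1)])
    se = entropy_difference(h, 128)
    expected = (255 / 256) * np.log2(255 / 256) + (1 / 256) * np.log2(1 / 256)
    assert se.s_delta == pytest.approx(expected, abs=1e-12)
    assert se.s_delta == pytest.approx(-0.03687, abs=5e-6)


def test_direct_delta_matches_oracle_and_closed_form(random_histograms, rng):
    checked = 0
    for h in random_histograms:
        nz = np.flatnonzero(h)
        for _ in range(5):
            l = int(rng.integers(nz[0] + 1, nz[-1] + 1))
            s_minus, s_plus, s_total, delta = naive_split_entropy(h.tolist(), l)
            se = entropy_difference(h, l)
            assert se.s_delta == pytest.approx(delta, abs=1e-9)
            assert se.s_minus == pytest.approx(s_minus, abs=1e-9)
            assert se.s_total == pytest.approx(s_total, abs=1e-9)
            assert se.s_delta == pytest.approx(se.closed_form(), abs=1e-9)
            checked += 1
    assert checked >= 200


def test_degenerate_split_signals():
    h = _hist([(100, 5), (120, 5)])
    with pytest.raises(DegenerateSplitError):
        entropy_difference(h, 50)   # empty left side


def test_best_split_matches_exhaustive_scan(random_histograms):
    for h in random_histograms:
        l_star, delta_star = best_split(h)
        best = (-np.inf, None)
        for l in range(1, 256):
            try:
                se = entropy_difference(h, l)
            except DegenerateSplitError:
                continue
            if se.s_delta > best[0]:
                best = (se.s_delta, l)
        assert l_star == best[1]
        assert delta_star == pytest.approx(best[0], abs=1e-12)


def test_best_split_separates_concentrated_mass_from_dispersed_tail():
    h = _hist([(5, 1000)] + [(120 + 10 * i, 3) for i in range(10)])
    l_star, _ = best_split(h)
    assert 5 < l_star <= 120


def test_best_split_requires_two_nonzero_bins():
    with pytest.raises(ValueError):
        best_split(_hist([(77, 123)]))


# --- monotonicity of the closed form (numerical versions of the identities) ---


def test_delta_increases_with_right_entropy():
    # left fixed and concentrated; right spread over ever more bins at equal mass
    for m_left, m_right in [(900, 100), (500, 500)]:
        lam = m_left / (m_left + m_right)
        deltas = []
        for width in range(1, 40):
            s_plus = np.log2(width)  # uniform right part over `width` bins
            deltas.append(closed_form_delta(lam, 0.0, s_plus))
        assert np.all(np.diff(deltas) >= -1e-12)


def test_delta_decreases_with_left_entropy():
    lam = 0.9
    deltas = [closed_form_delta(lam, np.log2(w), 3.0) for w in range(1, 40)]
    assert np.all(np.diff(deltas) <= 1e-12)


def test_delta_increases_with_lambda_above_critical_point():
    for s_minus, s_plus in [(0.0, 3.0), (1.0, 4.0), (2.0, 2.5)]:
        lam_crit = 1.0 / (1.0 + 2.0 ** (s_plus - s_minus))
        lams = np.linspace(lam_crit + 1e-6, 1 - 1e-6, 200)
        deltas = [closed_form_delta(l, s_minus, s_plus) for l in lams]
        assert np.all(np.diff(deltas) >= -1e-12)
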