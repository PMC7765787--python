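"""Uncertainty margins, top-K selection, the α gate, and the training loss."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kmargin.margin import (
    classification_loss,
    kmargin_select,
    margins_of,
    mean_top1_probability,
    most_confident,
    select_alpha_segments,
    uncertainty_margin,
)
from kmargin.types import ClassCatalog


def random_prob_table(rng, t, m):
    p = rng.dirichlet(np.ones(m), size=t)
    return p


def brute_force_selection(probs, k):
    """Independent oracle: enumerate all size-min(K,T) index subsets, choose the
    one minimizing total margin with lexicographic tie-break, then order its
    members by (margin, index)."""
    m = margins_of(probs)
    t = len(m)
    size = min(k, t)
    best = min(
        itertools.combinations(range(t), size),
        key=lambda idx: (sum(m[i] for i in idx), idx),
    )
    ordered = sorted(best, key=lambda i: (m[i], i))
    return [i + 1 for i in ordered]


class TestUncertaintyMargin:
    def test_clear_winner(self):
        assert uncertainty_margin([0.7, 0.2, 0.1]) == pytest.approx(-0.5)

    def test_uniform_ties_to_zero(self):
        assert uncertainty_margin([0.25] * 4) == pytest.approx(0.0)

    def test_extreme_confidence(self):
        assert uncertainty_margin([1.0, 0.0, 0.0]) == pytest.approx(-1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_margin([1.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_permuting_non_top_two(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(5))
        base = uncertainty_margin(p)
        order = np.argsort(p)
        rest = order[:-2]
        q = p.copy()
        q[rest] = q[rng.permutation(rest)]
        assert uncertainty_margin(q) == pytest.approx(base)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_range(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(rng.integers(2, 7)))
        assert -1.0 - 1e-12 <= uncertainty_margin(p) <= 1e-12


class TestMostConfident:
    def test_argmin_margin(self):
        cat = ClassCatalog(("a", "b"))
        probs = np.array([[0.75, 0.25], [0.55, 0.45], [0.95, 0.05]])
        t, label = most_confident(probs, cat)
        assert (t, label) == (3, "a")

    def test_single_segment(self):
        cat = ClassCatalog(("a", "b"))
        t, label = most_confident(np.array([[0.2, 0.8]]), cat)
        assert (t, label) == (1, "b")

    def test_tie_breaks_to_lowest_index(self):
        cat = ClassCatalog(("a", "b"))
        probs = np.array([[0.8, 0.2], [0.2, 0.8], [0.6, 0.4]])
        t, _ = most_confident(probs, cat)
        assert t == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            most_confident(np.zeros((0, 2)), ClassCatalog(("a", "b")))


class TestKMarginSelect:
    def test_hand_example(self):
        cat = ClassCatalog(("a", "b"))
        # margins -0.6, -0.1, -0.3, -0.5
        probs = np.array([[0.8, 0.2], [0.55, 0.45], [0.65, 0.35], [0.75, 0.25]])
        sel = kmargin_select(probs, 2, cat)
        assert list(sel.indices) == [1, 4]

    def test_k_equals_t_returns_all_in_margin_order(self):
        cat = ClassCatalog(("a", "b"))
        rng = np.random.default_rng(3)
        probs = random_prob_table(rng, 5, 2)
        sel = kmargin_select(probs, 5, cat)
        assert sorted(sel.indices) == [1, 2, 3, 4, 5]
        assert np.all(np.diff(sel.margins) >= 0)

    def test_k1_consistent_with_most_confident(self):
        cat = ClassCatalog(("a", "b", "c"))
        rng = np.random.default_rng(4)
        probs = random_prob_table(rng, 7, 3)
        sel = kmargin_select(probs, 1, cat)
        t, label = most_confident(probs, cat)
        assert (sel.indices[0], sel.labels[0]) == (t, label)

    def test_k_larger_than_t_clamps(self):
        cat = ClassCatalog(("a", "b"))
        sel = kmargin_select(np.array([[0.9, 0.1], [0.6, 0.4]]), 10, cat)
        assert len(sel) == 2

    def test_exhaustive_against_subset_oracle(self):
        """All T <= 6, all K <= T, 500 random probability tables."""
        cat = ClassCatalog(tuple("abcd"))
        rng = np.random.default_rng(42)
        for _ in range(500):
            t = int(rng.integers(1, 7))
            probs = random_prob_table(rng, t, 4)
            for k in range(1, t + 1):
                got = list(kmargin_select(probs, k, cat).indices)
                assert got == brute_force_selection(probs, k)


class TestAlphaGate:
    def test_mean_top1(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3]])
        assert mean_top1_probability(probs) == pytest.approx(0.8)

    def test_single_uniform_segment(self):
        assert mean_top1_probability(np.array([[0.5, 0.5]])) == pytest.approx(0.5)

    def test_upper_bound(self):
        probs = np.eye(3)
        assert mean_top1_probability(probs) == pytest.approx(1.0)

    def test_confident_record_takes_topk(self):
        cat = ClassCatalog(("a", "b"))
        probs = np.tile([0.8, 0.2], (5, 1))
        assert len(select_alpha_segments(probs, 3, cat)) == 3

    def test_unconfident_record_takes_all(self):
        cat = ClassCatalog(("a", "b", "c"))
        probs = np.tile([0.35, 0.33, 0.32], (5, 1))
        assert list(select_alpha_segments(probs, 3, cat)) == [1, 2, 3, 4, 5]

    def test_boundary_is_strict(self):
        cat = ClassCatalog(("a", "b"))
        probs = np.tile([0.5, 0.5], (4, 1))  # alpha exactly 0.5
        assert len(select_alpha_segments(probs, 2, cat)) == 4

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_output_size_is_k_or_t(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(1, 9))
        k = int(rng.integers(1, 6))
        probs = random_prob_table(rng, t, 3)
        out = select_alpha_segments(probs, k, ClassCatalog(("a", "b", "c")))
        assert len(out) in {min(k, t), t}


class TestClassificationLoss:
    def test_perfect_prediction_zero_loss(self):
        assert classification_loss(np.array([[1.0, 0.0]]), [0]) == pytest.approx(0.0)

    def test_closed_form_single_segment(self):
        p = math.exp(-1)
        loss = classification_loss(np.array([[p, 1 - p]]), [0])
        assert loss == pytest.approx(1.0)

    def test_pooled_mean_over_records(self):
        p1, p2 = math.exp(-1), math.exp(-3)
        probs = np.array([[p1, 1 - p1], [p2, 1 - p2]])
        assert classification_loss(probs, [0, 0]) == pytest.approx(2.0)

    def test_zero_probability_clipped_not_infinite(self):
        loss = classification_loss(np.array([[0.0, 1.0]]), [0])
        assert np.isfinite(loss) and loss > 0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.array([[0.5, 0.5]]), [0, 1])
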