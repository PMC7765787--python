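"""Sliding-window augmentation: dynamic strides, padding, windowing, fragments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kmargin.augment import (
    augment_dataset,
    compute_dynamic_strides,
    slide_windows,
    split_fragments,
    zero_pad,
)
from kmargin.types import AugmentationConfig, ClassCatalog, MonitoringRecord, Segment

from conftest import brute_force_window_count


class TestDynamicStrides:
    def test_skewed_af_composition(self, catalog4):
        # ceil(500 * count / 5050) per class, computed by hand
        table = compute_dynamic_strides(catalog4, 500)
        assert table.strides == {"N": 500, "A": 74, "O": 244, "P": 29}

    def test_equal_counts_all_get_max_stride(self):
        cat = ClassCatalog(("a", "b"), (10, 10))
        assert compute_dynamic_strides(cat, 7).strides == {"a": 7, "b": 7}

    def test_extreme_minority_floor_at_one(self):
        cat = ClassCatalog(("a", "b"), (1, 1000))
        table = compute_dynamic_strides(cat, 500)
        assert table.strides == {"a": 1, "b": 500}

    def test_zero_count_class_gets_max_stride(self):
        cat = ClassCatalog(("a", "b"), (0, 10))
        assert compute_dynamic_strides(cat, 500)["a"] == 500

    def test_all_zero_counts_rejected(self):
        cat = ClassCatalog(("a", "b"), (0, 0))
        with pytest.raises(ValueError):
            compute_dynamic_strides(cat, 500)

    @given(
        counts=st.lists(st.integers(1, 10_000), min_size=2, max_size=6),
        max_stride=st.integers(1, 2000),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_count_and_bounded(self, counts, max_stride):
        """Stride is nondecreasing in class count and lies in [1, M]; the most
        frequent class slides by exactly M — rare classes are oversampled."""
        labels = tuple(f"c{i}" for i in range(len(counts)))
        table = compute_dynamic_strides(ClassCatalog(labels, tuple(counts)), max_stride)
        by_count = sorted(zip(counts, labels))
        strides = [table[lab] for _, lab in by_count]
        assert strides == sorted(strides)
        assert all(1 <= s <= max_stride for s in strides)
        assert table[by_count[-1][1]] == max_stride


class TestZeroPad:
    def test_pads_tail_with_zeros(self):
        rec = np.ones((1, 5000))
        out = zero_pad(rec, 6000)
        assert out.shape == (1, 6000)
        assert np.all(out[:, :5000] == 1) and np.all(out[:, 5000:] == 0)

    def test_identity_at_exact_width(self):
        rec = np.arange(8.0)[None, :]
        assert np.array_equal(zero_pad(rec, 8), rec)

    def test_empty_input_gives_all_zeros(self):
        assert np.all(zero_pad(np.zeros((2, 0)), 10) == 0)

    def test_too_long_rejected(self):
        with pytest.raises(ValueError):
            zero_pad(np.zeros((1, 11)), 10)


class TestSlideWindows:
    def test_enumerated_offsets(self, ramp_record):
        segs = slide_windows(ramp_record, 6000, 300)
        assert [s.offset for s in segs] == [0, 300, 600]
        assert all(s.data.shape == (1, 6000) for s in segs)
        # window content equals the source at its offset
        assert segs[1].data[0, 0] == 300.0

    def test_exact_length_single_window(self):
        rec = MonitoringRecord("r", np.zeros((1, 6000)), 300.0, "N")
        assert len(slide_windows(rec, 6000, 17)) == 1

    def test_short_record_zero_padded(self):
        rec = MonitoringRecord("r", np.ones((1, 4000)), 300.0, "N")
        (seg,) = slide_windows(rec, 6000, 300)
        assert seg.data.shape == (1, 6000)
        assert np.all(seg.data[:, 4000:] == 0)

    @given(
        length=st.integers(1, 5000),
        window=st.integers(1, 2000),
        stride=st.integers(1, 700),
    )
    @settings(max_examples=300, deadline=None)
    def test_count_matches_enumeration_oracle(self, length, window, stride):
        rec = MonitoringRecord("r", np.zeros((1, length)), 1.0, "N")
        segs = slide_windows(rec, window, stride)
        assert len(segs) == brute_force_window_count(length, window, stride)

    def test_no_resampling_every_sample_from_source_or_zero(self, ramp_record):
        for seg in slide_windows(ramp_record, 6000, 250):
            expect = np.arange(seg.offset, seg.offset + 6000, dtype=float)
            assert np.array_equal(seg.data[0], expect)


class TestSplitFragments:
    def test_full_scale_fragment_count(self):
        seg = Segment("r", 1, np.zeros((1, 6000)), 0, "N")
        assert len(split_fragments(seg, 300)) == 20

    def test_identity_when_fragment_equals_window(self):
        data = np.random.default_rng(0).normal(size=(2, 64))
        seg = Segment("r", 1, data, 0, "N")
        (frag,) = split_fragments(seg, 64)
        assert np.array_equal(frag.data, data)

    def test_last_fragment_padded(self):
        seg = Segment("r", 1, np.ones((1, 700)), 0, "N")
        frags = split_fragments(seg, 300)
        assert len(frags) == 3
        assert np.all(frags[2].data[:, 100:] == 0)
        assert np.all(frags[2].data[:, :100] == 1)

    def test_fragments_tile_the_segment(self):
        data = np.arange(900.0)[None, :]
        seg = Segment("r", 1, data, 0, None)
        frags = split_fragments(seg, 300)
        recon = np.concatenate([f.data for f in frags], axis=1)
        assert np.array_equal(recon, data)


class TestAugmentDataset:
    @pytest.mark.parametrize(
        "stride,expected", [(74, 9), (500, 2)], ids=["minority", "majority"]
    )
    def test_training_yield_by_stride(self, stride, expected):
        # floor(600/stride) + 1 windows for a 6600-sample record, W=6000
        cat = ClassCatalog(("x", "y"), (stride, 500))  # max count 500 => stride ceil
        rec = MonitoringRecord("r", np.zeros((1, 6600)), 300.0, "x")
        cfg = AugmentationConfig(window=6000, max_stride=500)
        segs = augment_dataset([rec], cfg, cat, mode="train")
        assert len(segs) == expected

    def test_test_mode_uses_fixed_stride(self, ramp_record):
        cat = ClassCatalog(("N", "A"), (1, 1))
        cfg = AugmentationConfig(window=6000, max_stride=500, test_stride=300)
        segs = augment_dataset([ramp_record], cfg, cat, mode="test")
        assert len(segs) == 3

    def test_unlabeled_record_rejected_in_training(self):
        cat = ClassCatalog(("N", "A"), (1, 1))
        rec = MonitoringRecord("r", np.zeros((1, 100)), 1.0, label=None)
        with pytest.raises(ValueError):
            augment_dataset([rec], AugmentationConfig(window=50), cat, mode="train")

    def test_provenance_retained(self, ramp_record):
        cat = ClassCatalog(("N", "A"), (1, 1))
        cfg = AugmentationConfig(window=6000, test_stride=300)
        segs = augment_dataset([ramp_record], cfg, cat, mode="test")
        assert {s.record_id for s in segs} == {"ramp"}
        assert [s.t for s in segs] == [1, 2, 3]
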