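import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cartseg.objectives import (
    SearchSpaceError,
    apply_hard_thresholds,
    between_class_variance,
    compute_histogram,
    exhaustive_search,
    histogram_from_counts,
    kapur_entropy,
    multi_otsu,
)
from conftest import make_condensed_histogram


def uniform_histogram():
    return histogram_from_counts(np.ones(256, dtype=np.int64))


class TestHistogram:
    def test_constant_image(self):
        h = compute_histogram(np.full((10, 10), 7, np.uint8))
        assert h.counts[7] == 100 and h.probs[7] == 1.0

    def test_two_value_image(self):
        img = np.array([[0] * 50 + [255] * 50], np.uint8)
        h = compute_histogram(img)
        assert h.probs[0] == h.probs[255] == 0.5

    @given(st.integers(0, 2**31 - 1))
    def test_probs_normalized(self, seed):
        rng = np.random.default_rng(seed)
        h = compute_histogram(rng.integers(0, 256, size=(16, 16)))
        assert abs(h.probs.sum() - 1.0) < 1e-12


class TestHardThresholds:
    def test_two_value_split(self):
        img = np.array([[0, 255]], np.uint8)
        assert apply_hard_thresholds(img, [128]).tolist() == [[1, 2]]

    def test_threshold_value_goes_to_upper_region(self):
        assert apply_hard_thresholds(np.array([[99, 100]]), [100]).tolist() == [[1, 2]]

    def test_ramp_band_widths(self, all_intensities_image):
        lab = apply_hard_thresholds(all_intensities_image, [64, 128, 192])
        widths = [int((lab == l).sum()) for l in (1, 2, 3, 4)]
        assert widths == [64, 64, 64, 64]

    @given(st.integers(0, 2**31 - 1))
    def test_labels_partition_image(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(12, 12))
        tv = np.sort(rng.choice(np.arange(1, 256), size=3, replace=False))
        lab = apply_hard_thresholds(img, tv)
        assert lab.min() >= 1 and lab.max() <= 4
        assert sum(int((lab == l).sum()) for l in range(1, 5)) == img.size

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            apply_hard_thresholds(np.zeros((2, 2)), [10, 10])
        with pytest.raises(ValueError):
            apply_hard_thresholds(np.zeros((2, 2)), [0])


class TestKapurEntropy:
    def test_uniform_four_bins(self):
        counts = np.zeros(256, np.int64)
        counts[:4] = 25
        h = histogram_from_counts(counts)
        assert kapur_entropy(h, [2]) == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_single_intensity_is_zero(self):
        counts = np.zeros(256, np.int64)
        counts[0] = 10
        h = histogram_from_counts(counts)
        assert kapur_entropy(h, [100]) == 0.0

    def test_uniform_split_at_128(self):
        assert kapur_entropy(uniform_histogram(), [128]) == pytest.approx(
            2 * math.log(128), abs=1e-9
        )

    def test_invariant_to_image_size(self):
        small = compute_histogram(np.tile([0, 100, 200], 4))
        big = compute_histogram(np.tile([0, 100, 200], 4000))
        assert kapur_entropy(small, [50, 150]) == pytest.approx(
            kapur_entropy(big, [50, 150]), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    def test_entropy_upper_bound(self, seed):
        """Sum of L region entropies is at most L * ln(256/L)."""
        h = make_condensed_histogram(seed, n_active=(5, 200))
        rng = np.random.default_rng(seed)
        tv = np.sort(rng.choice(np.arange(1, 256), size=3, replace=False))
        assert kapur_entropy(h, tv) <= 4 * math.log(256 / 4) + 1e-9

    @given(st.integers(0, 2**31 - 1))
    def test_merge_entropy_bound(self, seed):
        """Merging two adjacent regions changes the sum by at most ln 2."""
        h = make_condensed_histogram(seed, n_active=(8, 16))
        rng = np.random.default_rng(seed)
        t1, t2 = np.sort(rng.choice(np.arange(1, 256), size=2, replace=False))
        merged = kapur_entropy(h, [t1])  # drop the inner threshold t2
        split = kapur_entropy(h, [t1, t2])
        # merged region entropy <= sum of part entropies + binary branch entropy
        assert merged <= split + math.log(2) + 1e-9


class TestExhaustiveSearch:
    def test_two_delta_bcv_tie_break(self):
        counts = np.zeros(256, np.int64)
        counts[0] = counts[255] = 50
        h = histogram_from_counts(counts)
        tv, f = exhaustive_search(h, 1, "between_class_variance")
        assert tv.tolist() == [1]
        assert f == pytest.approx(0.25 * 255**2, abs=1e-9)

    def test_uniform_kapur_optimum(self):
        tv, f = exhaustive_search(uniform_histogram(), 1, "kapur")
        assert tv.tolist() == [128]
        assert f == pytest.approx(2 * math.log(128), abs=1e-9)

    def test_zero_thresholds(self):
        h = uniform_histogram()
        tv, f = exhaustive_search(h, 0, "kapur")
        assert tv.size == 0
        assert f == pytest.approx(math.log(256), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2])
    def test_matches_full_enumeration(self, n, condensed_histogram):
        h = condensed_histogram
        tv, f = exhaustive_search(h, n, "kapur")
        best, best_tv = -1.0, None
        for combo in itertools.combinations(range(1, 256), n):
            v = kapur_entropy(h, list(combo))
            if v > best + 1e-12:
                best, best_tv = v, combo
        assert f == pytest.approx(best, abs=1e-9)
        assert tuple(tv) == best_tv

    def test_empty_middle_region_handled(self):
        # two active bins, two thresholds: every partition scores zero and
        # the lexicographically smallest valid vector wins
        counts = np.zeros(256, np.int64)
        counts[0] = counts[255] = 10
        h = histogram_from_counts(counts)
        tv, f = exhaustive_search(h, 2, "kapur")
        assert tv.tolist() == [1, 2] and f == 0.0

    def test_guard_refuses_wide_search(self):
        with pytest.raises(SearchSpaceError):
            exhaustive_search(uniform_histogram(), 4, "kapur")

    def test_unknown_objective(self):
        with pytest.raises(ValueError):
            exhaustive_search(uniform_histogram(), 1, "dice")


class TestMultiOtsu:
    def test_two_delta_single_threshold(self):
        counts = np.zeros(256, np.int64)
        counts[0] = counts[255] = 50
        h = histogram_from_counts(counts)
        assert multi_otsu(h, 1).tolist() == [1]

    @pytest.mark.parametrize("seed", range(5))
    def test_single_threshold_equals_exhaustive(self, seed):
        h = make_condensed_histogram(seed, n_active=(5, 200))
        tv, _ = exhaustive_search(h, 1, "between_class_variance")
        assert multi_otsu(h, 1).tolist() == tv.tolist()

    def test_equal_area_widths(self):
        """With 4 thresholds each lives in its own width-64 area."""
        h = make_condensed_histogram(3, n_active=(100, 200))
        tv = multi_otsu(h, 4)
        for i, t in enumerate(tv):
            assert 64 * i < t <= 64 * (i + 1)

    def test_empty_area_midpoint_fallback(self):
        counts = np.zeros(256, np.int64)
        counts[200:256] = 5  # first of two areas empty
        h = histogram_from_counts(counts)
        tv = multi_otsu(h, 2)
        assert tv[0] == 64  # midpoint of [0, 128)

    def test_between_class_variance_value(self):
        counts = np.zeros(256, np.int64)
        counts[0] = counts[255] = 50
        h = histogram_from_counts(counts)
        assert between_class_variance(h, [128]) == pytest.approx(0.25 * 255**2)
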