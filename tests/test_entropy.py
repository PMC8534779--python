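"""Unit and property tests for local histograms and reduced entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrotex.entropy import (
    EntropySpec,
    HistogramSpec,
    LocalHistogram,
    SpecError,
    WindowSpec,
    bgs_entropy,
    entropy_transform,
    entropy_transform_naive,
    local_histogram,
    reduced_entropy,
    tsallis_entropy,
)


def norm_hist(mass):
    mass = np.asarray(mass, dtype=float)
    return LocalHistogram(mass=mass, count_total=int(round(mass.sum())), normalized=True)


class TestLocalHistogram:
    def test_constant_window_concentrates_in_one_bin(self):
        img = np.full((3, 3), 10)
        h = local_histogram(img, (1, 1), WindowSpec(radius=1), HistogramSpec(bin_width=64))
        assert h.mass.tolist() == [1.0, 0.0, 0.0, 0.0]
        assert h.count_total == 9

    def test_half_open_bin_edges(self):
        # 0 and 63 share the first bin, 64 opens the second, 255 tops the last
        img = np.array([[0, 63], [64, 255]])
        h = local_histogram(
            img, (0, 0), WindowSpec(radius=1, border_mode="clamp"),
            HistogramSpec(bin_width=64, normalize=False),
        )
        # clamp-padded 3x3 window around (0,0) holds {0:x4, 63:x2, 64:x2, 255:x1}
        assert h.mass.tolist() == [6.0, 2.0, 0.0, 1.0]
        assert h.count_total == 9

    @pytest.mark.parametrize("bin_width", [16, 32, 64])
    def test_normalized_mass_sums_to_one(self, rng, bin_width):
        img = rng.integers(0, 256, (9, 9))
        h = local_histogram(img, (4, 4), WindowSpec(radius=2), HistogramSpec(bin_width))
        assert h.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_center_out_of_bounds_raises(self):
        with pytest.raises(IndexError):
            local_histogram(np.zeros((4, 4), int), (4, 0), WindowSpec(1), HistogramSpec(64))

    def test_bin_width_must_divide_levels(self):
        with pytest.raises(SpecError):
            HistogramSpec(bin_width=48)


class TestEntropyForms:
    @pytest.mark.parametrize("q", [0.5, 2.0, 3.0])
    def test_degenerate_distribution_has_zero_entropy(self, q):
        assert tsallis_entropy([1.0, 0.0, 0.0], EntropySpec(q=q)) == pytest.approx(0.0)

    def test_tsallis_uniform_closed_form(self):
        # k_B (1 - B^(1-q)) / (q - 1); B = 2, q = 2 -> 0.5
        assert tsallis_entropy([0.5, 0.5], EntropySpec(q=2)) == 0.5
        for B in (3, 8):
            for q in (0.5, 1.5, 2.0):
                expected = (1 - B ** (1 - q)) / (q - 1)
                got = tsallis_entropy(np.full(B, 1 / B), EntropySpec(q=q))
                assert got == pytest.approx(expected, abs=1e-12)

    def test_tsallis_rejects_q_equal_one(self):
        with pytest.raises(ValueError, match="q = 1"):
            tsallis_entropy([0.5, 0.5], EntropySpec(q=1.0))

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            tsallis_entropy([1.2, -0.2], EntropySpec(q=2))
        with pytest.raises(ValueError):
            bgs_entropy([1.2, -0.2])

    def test_bgs_values(self):
        assert bgs_entropy([1.0, 0.0]) == 0.0
        assert bgs_entropy([0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-12)
        assert bgs_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2), abs=1e-12)

    def test_tsallis_approaches_bgs_near_q_one(self, rng):
        """Numerical q -> 1 limit on random distributions."""
        for _ in range(100):
            p = rng.random(rng.integers(2, 20))
            p /= p.sum()
            h = bgs_entropy(p)
            for q in (1 - 1e-6, 1 + 1e-6):
                assert abs(tsallis_entropy(p, EntropySpec(q=q)) - h) < 1e-5 * abs(h)


class TestReducedEntropy:
    def test_single_bin_is_one(self):
        h = norm_hist([0, 1.0, 0, 0])
        assert reduced_entropy(h, EntropySpec(q=2)) == 1.0

    @pytest.mark.parametrize("B,q", [(4, 2.0), (8, 0.5), (2, 1.5)])
    def test_uniform_closed_form(self, B, q):
        h = norm_hist(np.full(B, 1 / B))
        assert reduced_entropy(h, EntropySpec(q=q)) == pytest.approx(B ** (1 - q), abs=1e-12)

    def test_direct_evaluation(self):
        h = norm_hist([0.5, 0.5])
        assert reduced_entropy(h, EntropySpec(q=0.5)) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_q1_default_is_shannon(self):
        h = norm_hist([0.5, 0.25, 0.25])
        got = reduced_entropy(h, EntropySpec(q=1.0))
        assert got == pytest.approx(1.5 * np.log(2), abs=1e-12)

    def test_q1_raw_mode_is_constant(self):
        h = norm_hist([0.7, 0.3])
        assert reduced_entropy(h, EntropySpec(q=1.0, q1_mode="raw")) == pytest.approx(1.0)

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=12),
           st.sampled_from([0.5, 1.5, 2.0]))
    @settings(deadline=None)
    def test_permutation_invariance(self, masses, q):
        p = np.array(masses) / np.sum(masses)
        h = norm_hist(p)
        hp = norm_hist(np.random.default_rng(0).permutation(p))
        assert reduced_entropy(h, EntropySpec(q=q)) == pytest.approx(
            reduced_entropy(hp, EntropySpec(q=q)), abs=1e-12
        )

    @pytest.mark.parametrize("q", [0.25, 0.5, 0.75])
    def test_uniform_maximizes_below_one(self, rng, q):
        """Among B-bin histograms the uniform one maximizes S'_q for q < 1."""
        for B in (2, 5, 9):
            bound = B ** (1 - q)
            for _ in range(50):
                p = rng.random(B) + 1e-9
                p /= p.sum()
                assert reduced_entropy(norm_hist(p), EntropySpec(q=q)) <= bound + 1e-12

    @pytest.mark.parametrize("q", [1.5, 2.0, 3.0])
    def test_uniform_minimizes_above_one(self, rng, q):
        for B in (2, 5, 9):
            bound = B ** (1 - q)
            for _ in range(50):
                p = rng.random(B) + 1e-9
                p /= p.sum()
                assert reduced_entropy(norm_hist(p), EntropySpec(q=q)) >= bound - 1e-12

    def test_monotone_nonincreasing_in_q(self, rng):
        """For a fixed probability vector, sum p^q never grows with q."""
        qs = np.linspace(0.1, 3.0, 15)
        for _ in range(20):
            p = rng.random(8)
            p /= p.sum()
            vals = [reduced_entropy(norm_hist(p), EntropySpec(q=q)) for q in qs]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestEntropyTransform:
    def test_constant_image_maps_to_one(self):
        em = entropy_transform(np.full((6, 7), 40), spec=EntropySpec(q=1.7))
        assert em.values.shape == (6, 7)
        assert np.all(em.values == 1.0)

    def test_checkerboard_interior_value(self):
        """3x3 windows on a {0,255} checkerboard split 5/4 across two bins."""
        idx = np.indices((10, 10)).sum(axis=0)
        img = (idx % 2) * 255
        em = entropy_transform(img, WindowSpec(1), HistogramSpec(32), EntropySpec(q=2))
        expected = (25 + 16) / 81
        assert np.allclose(em.values[1:-1, 1:-1], expected, atol=1e-12)

    @pytest.mark.parametrize("q", [0.5, 1.0, 1.5, 2.0])
    @pytest.mark.parametrize("r", [1, 2])
    @pytest.mark.parametrize("border", ["reflect", "clamp"])
    def test_matches_naive_oracle(self, rng, q, r, border):
        img = rng.integers(0, 256, (16, 16))
        win, hist, spec = WindowSpec(r, border), HistogramSpec(32), EntropySpec(q=q)
        fast = entropy_transform(img, win, hist, spec)
        slow = entropy_transform_naive(img, win, hist, spec)
        np.testing.assert_array_equal(fast.values, slow.values)

    def test_raw_mode_matches_naive_oracle(self, rng):
        img = rng.integers(0, 256, (12, 12))
        hist = HistogramSpec(64, normalize=False)
        fast = entropy_transform(img, WindowSpec(2), hist, EntropySpec(q=2))
        slow = entropy_transform_naive(img, WindowSpec(2), hist, EntropySpec(q=2))
        np.testing.assert_array_equal(fast.values, slow.values)

    @pytest.mark.parametrize("q,lo,hi", [(2.0, 0.0, 1.0), (0.5, 1.0, 8 ** 0.5)])
    def test_value_range(self, rng, q, lo, hi):
        """q > 1 maps into (0, 1]; q < 1 into [1, n_bins^(1-q)]."""
        img = rng.integers(0, 256, (20, 20))
        em = entropy_transform(img, WindowSpec(2), HistogramSpec(32), EntropySpec(q=q))
        assert np.all(np.isfinite(em.values))
        assert em.values.min() > lo - 1e-12 and em.values.max() <= hi + 1e-12

    def test_provenance_recorded(self, rng):
        img = rng.integers(0, 256, (8, 8))
        em = entropy_transform(img, WindowSpec(3), HistogramSpec(16), EntropySpec(q=0.75))
        assert (em.q, em.radius, em.bin_width) == (0.75, 3, 16)


class TestSpecValidation:
    @pytest.mark.parametrize("bad", [0, -1])
    def test_radius_positive(self, bad):
        with pytest.raises(SpecError):
            WindowSpec(radius=bad)

    def test_border_mode_checked(self):
        with pytest.raises(SpecError):
            WindowSpec(border_mode="wrap")

    @pytest.mark.parametrize("bad_q", [0.0, -0.5])
    def test_q_positive(self, bad_q):
        with pytest.raises(SpecError):
            EntropySpec(q=bad_q)

    def test_intensity_range_checked(self):
        with pytest.raises(ValueError):
            entropy_transform(np.array([[0, 300]]))
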