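"""SAX symbolization: z-norm, PAA, breakpoints, binning, window shifting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chisquare, norm

from nirsax.sax import (
    SaxConfig,
    breakpoints,
    paa,
    symbolize,
    triple_window_shift,
    znorm,
)


class TestZnorm:
    def test_small_example(self):
        assert np.allclose(znorm([1, 2, 3]), [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_guard(self):
        assert np.all(znorm([4.2] * 10) == 0)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50))
    def test_zero_mean_unit_population_std(self, y):
        out = znorm(y)
        if np.any(out != 0):
            assert abs(out.mean()) < 1e-10
            assert abs(out.std() - 1.0) < 1e-10


def brute_paa(y, w):
    """Fractional-boundary PAA by explicit per-sample weight accounting."""
    n = len(y)
    out = np.zeros(w)
    for k in range(w):
        a, b = k * n / w, (k + 1) * n / w
        total = 0.0
        for i in range(n):
            overlap = max(0.0, min(i + 1, b) - max(i, a))
            total += overlap * y[i]
        out[k] = total / (n / w)
    return out


class TestPaa:
    def test_identity_when_w_equals_n(self):
        y = np.random.default_rng(0).standard_normal(1300)
        assert np.array_equal(paa(y, 1300), y)

    def test_block_means_when_w_divides_n(self):
        y = np.random.default_rng(1).standard_normal(1300)
        got = paa(y, 100)
        expected = [np.mean(y[13 * k: 13 * (k + 1)]) for k in range(100)]
        assert np.allclose(got, expected, atol=1e-12)

    def test_fractional_boundaries_match_weight_oracle(self):
        y = np.random.default_rng(2).standard_normal(130)
        assert np.allclose(paa(y, 37), brute_paa(y, 37), atol=1e-9)

    def test_w_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            paa(np.zeros(10), 11)

    def test_mean_preserved_when_w_divides_n(self):
        y = znorm(np.random.default_rng(3).standard_normal(1300))
        assert abs(np.mean(paa(y, 100))) < 1e-9


class TestBreakpoints:
    def test_median_split(self):
        assert np.array_equal(breakpoints(2), [0.0])

    def test_quartiles(self):
        expected = [norm.ppf(q) for q in (0.25, 0.5, 0.75)]
        assert np.allclose(breakpoints(4), expected, atol=1e-12)

    @pytest.mark.parametrize("a", range(2, 12))
    def test_equiprobable_mass(self, a):
        bp = np.concatenate(([-np.inf], breakpoints(a), [np.inf]))
        masses = np.diff(norm.cdf(bp))
        assert np.all(np.abs(masses - 1.0 / a) < 1e-9)

    @pytest.mark.parametrize("a", range(2, 12))
    def test_exact_antisymmetry(self, a):
        bp = breakpoints(a)
        assert np.all(bp + bp[::-1] == 0.0)

    def test_too_small_alphabet_rejected(self):
        with pytest.raises(ValueError):
            breakpoints(1)


class TestSymbolize:
    def test_constant_input_middle_bin(self):
        s = symbolize(np.full(100, 9.9), SaxConfig(n_segments=10, alphabet_size=8))
        # znorm guard maps to 0, which sits on the central breakpoint and
        # takes the lower symbol: D (=4) for an 8-letter alphabet
        assert s.symbols == "D" * 10
        assert np.all(s.numeric == 4)

    def test_steep_ramp_binary_split(self):
        s = symbolize(np.linspace(0, 1, 100), SaxConfig(n_segments=10, alphabet_size=2))
        assert s.symbols == "AAAAABBBBB"

    def test_monotone_input_monotone_word(self):
        y = np.cumsum(np.random.default_rng(4).random(200))
        s = symbolize(y, SaxConfig(n_segments=50, alphabet_size=8))
        assert np.all(np.diff(s.numeric) >= 0)

    def test_numeric_is_one_based_rank(self):
        s = symbolize(np.random.default_rng(5).standard_normal(64),
                      SaxConfig(n_segments=16, alphabet_size=8))
        assert np.all((s.numeric >= 1) & (s.numeric <= 8))
        assert s.symbols == "".join("ABCDEFGH"[v - 1] for v in s.numeric)

    def test_offset_scale_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(130)
        cfg = SaxConfig(n_segments=130, alphabet_size=6)
        base = symbolize(y, cfg)
        for a, b in [(3.0, -2.0), (0.01, 100.0)]:
            assert symbolize(a * y + b, cfg).symbols == base.symbols

    def test_gaussian_noise_gives_uniform_symbol_histogram(self):
        """Equiprobable breakpoints: chi-square uniformity at alpha=0.01."""
        y = np.random.default_rng(7).standard_normal(10_000)
        s = symbolize(y, SaxConfig(n_segments=10_000, alphabet_size=8))
        counts = np.bincount(s.numeric, minlength=9)[1:]
        assert chisquare(counts).pvalue > 0.01


class TestTripleWindowShift:
    def _word(self, n=10):
        return np.arange(1, n + 1)

    def test_zero_stride_three_copies(self):
        wins = triple_window_shift(self._word(), stride=0)
        assert len(wins) == 3
        for w in wins:
            assert np.array_equal(w, self._word())

    def test_window_index_arithmetic(self):
        wins = triple_window_shift(self._word(10), stride=2)
        assert np.array_equal(wins[0], [1, 2, 3, 4, 5, 6])
        assert np.array_equal(wins[1], [3, 4, 5, 6, 7, 8])
        assert np.array_equal(wins[2], [5, 6, 7, 8, 9, 10])

    def test_default_stride_gives_80_percent_windows(self):
        wins = triple_window_shift(self._word(100))
        assert all(len(w) == 80 for w in wins)

    def test_concat_mode_single_sequence(self):
        out = triple_window_shift(self._word(10), mode="concat", stride=2)
        assert len(out) == 1 and len(out[0]) == 18

    def test_augment_triples_instances(self):
        words = [self._word(20) for _ in range(7)]
        instances = [w for word in words for w in triple_window_shift(word, stride=2)]
        assert len(instances) == 21

    def test_oversized_stride_rejected(self):
        with pytest.raises(ValueError, match="stride"):
            triple_window_shift(self._word(10), stride=5)
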