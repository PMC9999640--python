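"""EMD core: extrema, envelopes, sifting, full decomposition."""

import numpy as np
import pytest

from ecgrt import (NotEnoughExtremaError, SiftConfig, decompose,
                   envelope_mean, find_extrema, sift_imf)
from ecgrt.hht import mean_frequency

from conftest import FS


def brute_force_extrema(x):
    """Independent O(n^2)-naive scan used as the oracle for plateau handling."""
    maxima, minima = [], []
    n = len(x)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j + 1 < n and i - 1 >= 0:
            if x[i] > x[i - 1] and x[i] > x[j + 1]:
                maxima.append((i + j) // 2)
            elif x[i] < x[i - 1] and x[i] < x[j + 1]:
                minima.append((i + j) // 2)
        i = j + 1
    return maxima, minima


class TestFindExtrema:
    def test_single_period_sine(self):
        t = np.linspace(0, 1, 100, endpoint=False)
        x = np.sin(2 * np.pi * t)
        max_i, _, min_i, _ = find_extrema(x)
        assert max_i.size == 1 and min_i.size == 1

    def test_monotone_ramp_has_no_extrema(self):
        max_i, _, min_i, _ = find_extrema(np.linspace(0, 1, 50))
        assert max_i.size == 0 and min_i.size == 0

    def test_plateau_collapses_to_midpoint(self):
        max_i, max_v, _, _ = find_extrema(np.array([0.0, 1.0, 1.0, 1.0, 0.0]))
        assert list(max_i) == [2]
        assert list(max_v) == [1.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_quantized_noise(self, seed):
        """Quantization creates plateaus; compare with the naive scan."""
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=300), 1)
        max_i, _, min_i, _ = find_extrema(x)
        bf_max, bf_min = brute_force_extrema(x)
        assert list(max_i) == bf_max
        assert list(min_i) == bf_min

    def test_maxima_and_minima_alternate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        max_i, _, min_i, _ = find_extrema(x)
        kinds = sorted([(i, "M") for i in max_i] + [(i, "m") for i in min_i])
        for (_, a), (_, b) in zip(kinds, kinds[1:]):
            assert a != b


class TestEnvelopeMean:
    def test_pure_sine_mean_near_zero(self):
        t = np.arange(2500) / FS
        x = np.sin(2 * np.pi * 10 * t)
        m = envelope_mean(x)
        interior = slice(125, -125)  # outside the boundary region
        assert np.max(np.abs(m[interior])) < 0.05

    def test_constant_signal_raises(self):
        with pytest.raises(NotEnoughExtremaError):
            envelope_mean(np.ones(100))

    def test_offset_sine_mean_near_offset(self):
        t = np.arange(2500) / FS
        c = 0.7
        x = np.sin(2 * np.pi * 10 * t) + c
        m = envelope_mean(x)
        interior = slice(125, -125)
        assert np.max(np.abs(m[interior] - c)) < 0.05

    def test_envelopes_pass_through_knots(self):
        from ecgrt.emd import envelopes
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        max_i, max_v, min_i, min_v = find_extrema(x)
        upper, lower = envelopes(x, (max_i, max_v, min_i, min_v))
        np.testing.assert_allclose(upper[max_i], x[max_i], atol=1e-9)
        np.testing.assert_allclose(lower[min_i], x[min_i], atol=1e-9)


def imf_property_holds(imf):
    """|#extrema - #zero-crossings| <= 1 (the defining IMF condition)."""
    max_i, _, min_i, _ = find_extrema(imf)
    n_ext = max_i.size + min_i.size
    sign = np.sign(imf)
    sign = sign[sign != 0]
    n_zc = int(np.sum(sign[:-1] != sign[1:]))
    return abs(n_ext - n_zc) <= 1


class TestSiftImf:
    def test_sine_is_already_an_imf(self):
        t = np.arange(2500) / FS
        x = np.sin(2 * np.pi * 10 * t)
        imf, iters = sift_imf(x)
        assert iters <= 2
        rms = np.sqrt(np.mean((imf - x) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_two_tone_first_imf_is_fast_tone(self):
        """Two-tone separation oracle: first IMF tracks the 25-Hz tone."""
        t = np.arange(2500) / FS
        fast = np.sin(2 * np.pi * 25 * t)
        slow = np.sin(2 * np.pi * 3 * t)
        imf, _ = sift_imf(fast + slow)
        interior = slice(125, -125)  # exclude 0.5-s edges
        r = np.corrcoef(imf[interior], fast[interior])[0, 1]
        assert r > 0.95

    def test_white_noise_imf_satisfies_imf_property(self):
        rng = np.random.default_rng(12)
        imf, _ = sift_imf(rng.normal(size=2500))
        assert imf_property_holds(imf)

    def test_constant_input_raises(self):
        with pytest.raises(NotEnoughExtremaError):
            sift_imf(np.ones(100))


class TestDecompose:
    def test_zero_signal_degenerates_cleanly(self):
        s = decompose(np.zeros(100), SiftConfig(pad_to_max=False))
        assert len(s) == 0 and s.n_natural == 0
        assert not np.any(s.residual)

    def test_reconstruction_is_exact(self, ecg_imfset, ecg_window):
        recon = ecg_imfset.reconstruct()
        scale = np.max(np.abs(ecg_window.samples))
        assert np.max(np.abs(recon - ecg_window.samples)) < 1e-8 * scale

    def test_components_satisfy_imf_property(self, ecg_imfset):
        for c in ecg_imfset.components[:ecg_imfset.n_natural]:
            assert imf_property_holds(c)

    def test_ecg_window_yields_deep_decomposition(self, ecg_imfset):
        assert ecg_imfset.n_natural >= 6
        assert len(ecg_imfset.components) == 8

    def test_frequency_ordering_c1_fastest(self, ecg_imfset):
        fs = ecg_imfset.sampling_rate
        f1 = mean_frequency(ecg_imfset.components[0], fs)
        f4 = mean_frequency(ecg_imfset.components[3], fs)
        assert f1 > f4

    def test_mean_frequency_nonincreasing_over_components(self, ecg_imfset):
        fs = ecg_imfset.sampling_rate
        freqs = [mean_frequency(c, fs)
                 for c in ecg_imfset.components[:ecg_imfset.n_natural]]
        assert all(a >= b - 1e-9 for a, b in zip(freqs, freqs[1:]))

    def test_padding_policy_gives_exactly_eight(self):
        t = np.arange(2500) / FS
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 1 * t)
        s = decompose(x, SiftConfig())
        assert len(s.components) == 8
        assert s.n_natural < 8
        for c in s.components[s.n_natural:]:
            assert not np.any(c)

    @pytest.mark.parametrize("f_fast,f_slow", [(25, 3), (30, 5), (20, 2)])
    def test_two_tone_components_match_closed_form(self, f_fast, f_slow):
        """Independent oracle: on a well-separated two-tone signal the true
        components are the analytic tones themselves; the first two IMFs
        must correlate > 0.9 with them."""
        t = np.arange(2500) / FS
        fast = np.sin(2 * np.pi * f_fast * t)
        slow = np.sin(2 * np.pi * f_slow * t)
        s = decompose(fast + slow, SiftConfig())
        interior = slice(125, -125)
        r1 = np.corrcoef(s.components[0][interior], fast[interior])[0, 1]
        r2 = np.corrcoef(s.components[1][interior], slow[interior])[0, 1]
        assert r1 > 0.9 and r2 > 0.9
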