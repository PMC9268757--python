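"""Cross-covariance features vs brute-force oracles, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imspeech import (SmoothingKernel, ccv_frequency, ccv_time,
                      channel_spectrum, cross_covariance, expected_value,
                      smooth_spectrum, standardize_features)
from imspeech.features import Spectrum

from .conftest import make_window


# -- independent oracles -----------------------------------------------------

def cov_oracle(x1, x2):
    """Nested-loop double sum for the zero-lag population covariance."""
    w = len(x1)
    m1 = sum(x1) / w
    m2 = sum(x2) / w
    return sum((x1[i] - m1) * (x2[i] - m2) for i in range(w)) / w


def dft_oracle(x):
    """Direct O(n²) DFT magnitude, one-sided."""
    n = len(x)
    bins = n // 2 + 1
    out = np.empty(bins)
    for k in range(bins):
        acc = sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n))
        out[k] = abs(acc)
    return out


def windowed_mean_oracle(bins, width):
    """Moving average with replicated boundary bins."""
    half = width // 2
    padded = np.concatenate([[bins[0]] * half, bins, [bins[-1]] * half])
    return np.array([padded[i:i + width].mean() for i in range(len(bins))])


class TestScalarOps:
    def test_expected_value_examples(self):
        assert expected_value([1, 2, 3]) == 2
        assert expected_value(np.full(17, 4.2)) == pytest.approx(4.2)
        with pytest.raises(ValueError):
            expected_value([])

    def test_expected_value_matches_summation(self, rng):
        x = rng.normal(size=7)
        assert expected_value(x) == pytest.approx(sum(x) / 7, rel=1e-15)

    def test_cross_covariance_population_variance(self):
        # deviations −1, 0, 1 → population variance 2/3
        assert cross_covariance([1, 2, 3], [1, 2, 3]) == pytest.approx(2 / 3)

    def test_cross_covariance_constant_is_zero(self, rng):
        assert cross_covariance(np.full(10, 3.0), rng.normal(size=10)) == 0.0

    def test_cross_covariance_errors(self):
        with pytest.raises(ValueError):
            cross_covariance([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            cross_covariance([1], [2])

    def test_cross_covariance_vs_bruteforce_many_pairs(self, rng):
        for _ in range(200):
            x1, x2 = rng.normal(size=(2, 50))
            expected = cov_oracle(list(x1), list(x2))
            assert cross_covariance(x1, x2) == pytest.approx(expected, rel=1e-12)


class TestTimeDomainMatrix:
    def test_shape_is_channels_squared(self, rng):
        win = make_window(rng, n_channels=62, n_samples=250)
        assert ccv_time(win).values.shape == (62, 62)

    def test_duplicated_channel_symmetry(self, rng):
        win = make_window(rng, n_channels=4, n_samples=50)
        data = win.data.copy()
        data[2] = data[1]
        dup = type(win)(data=data, fs=win.fs, label=win.label,
                        subject_id=win.subject_id, session_id=win.session_id,
                        recording_index=0, window_index=0)
        m = ccv_time(dup).values
        np.testing.assert_allclose(m[1], m[2], rtol=1e-12)
        assert m[1, 1] == pytest.approx(m[1, 2], rel=1e-12)

    def test_entrywise_bruteforce(self, rng):
        win = make_window(rng, n_channels=5, n_samples=40)
        m = ccv_time(win).values
        for i in range(5):
            for j in range(5):
                expected = cov_oracle(list(win.data[i]), list(win.data[j]))
                assert m[i, j] == pytest.approx(expected, rel=1e-10)

    def test_symmetric_positive_semidefinite(self, rng):
        for _ in range(20):
            win = make_window(rng, n_channels=6, n_samples=32)
            m = ccv_time(win).values
            np.testing.assert_allclose(m, m.T, atol=1e-10 * np.abs(m).max())
            eigs = np.linalg.eigvalsh(m)
            assert eigs.min() >= -1e-8 * np.trace(m)


class TestSpectrum:
    @pytest.mark.parametrize("n", [16, 50, 64, 250])
    def test_matches_naive_dft(self, rng, n):
        win = make_window(rng, n_channels=2, n_samples=n)
        spec = channel_spectrum(win)
        for ch in range(2):
            np.testing.assert_allclose(spec.mag[ch], dft_oracle(win.data[ch]),
                                       rtol=1e-9, atol=1e-9)

    def test_dc_only_constant_signal(self):
        rng = np.random.default_rng(0)
        win = make_window(rng, n_channels=2, n_samples=32)
        win.data[:] = 2.5
        spec = channel_spectrum(win)
        assert spec.mag[0, 0] == pytest.approx(32 * 2.5)
        np.testing.assert_allclose(spec.mag[0, 1:], 0, atol=1e-10)

    def test_single_tone_magnitude(self):
        n, k = 64, 5
        t = np.arange(n)
        rng = np.random.default_rng(0)
        win = make_window(rng, n_channels=2, n_samples=n)
        win.data[0] = np.cos(2 * np.pi * k * t / n)
        spec = channel_spectrum(win)
        assert spec.mag[0, k] == pytest.approx(n / 2)
        others = np.delete(spec.mag[0], k)
        np.testing.assert_allclose(others, 0, atol=1e-9)

    def test_parseval(self, rng):
        win = make_window(rng, n_channels=3, n_samples=50)
        spec = channel_spectrum(win)
        # rebuild the two-sided magnitudes: interior one-sided bins appear twice
        n = spec.n
        for ch in range(3):
            two_sided = np.concatenate([spec.mag[ch],
                                        spec.mag[ch, 1:(n + 1) // 2][::-1]])
            lhs = np.sum(two_sided ** 2)
            rhs = n * np.sum(win.data[ch] ** 2)
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_bin_resolution(self, rng):
        win = make_window(rng, n_channels=2, n_samples=250, fs=1000.0)
        spec = channel_spectrum(win)
        assert spec.n_bins == 126
        assert spec.bin_resolution == pytest.approx(4.0)


class TestSmoothing:
    def _spectrum(self, mags):
        mags = np.atleast_2d(np.asarray(mags, dtype=float))
        n = 2 * (mags.shape[1] - 1)
        return Spectrum(mag=mags, n=n, fs=float(n))

    def test_width_one_is_identity(self, rng):
        win = make_window(rng, n_channels=3, n_samples=64)
        spec = channel_spectrum(win)
        out = smooth_spectrum(spec, SmoothingKernel(1))
        np.testing.assert_array_equal(out.mag, spec.mag)

    def test_constant_spectrum_unchanged(self):
        spec = self._spectrum(np.full(10, 3.7))
        out = smooth_spectrum(spec, SmoothingKernel(3))
        np.testing.assert_allclose(out.mag, 3.7)
        # constants also preserve the total exactly
        assert out.mag.sum() == pytest.approx(spec.mag.sum())

    @pytest.mark.parametrize("width", [3, 5])
    def test_matches_windowed_mean_oracle(self, rng, width):
        bins = np.abs(rng.normal(size=17))
        out = smooth_spectrum(self._spectrum(bins), SmoothingKernel(width))
        np.testing.assert_allclose(out.mag[0],
                                   windowed_mean_oracle(bins, width),
                                   rtol=1e-12)

    def test_edge_replication_example(self):
        out = smooth_spectrum(self._spectrum([0, 3, 0, 0]), SmoothingKernel(3))
        np.testing.assert_allclose(out.mag[0], [1, 1, 1, 0])

    def test_preserves_nonnegativity(self, rng):
        win = make_window(rng, n_channels=2, n_samples=64)
        out = smooth_spectrum(channel_spectrum(win), SmoothingKernel(5))
        assert (out.mag >= 0).all()

    def test_invalid_kernels(self):
        with pytest.raises(ValueError):
            SmoothingKernel(2)
        with pytest.raises(ValueError):
            SmoothingKernel(0)
        with pytest.raises(ValueError, match="exceeds"):
            smooth_spectrum(self._spectrum([1.0, 2.0]), SmoothingKernel(5))


class TestFrequencyDomainMatrix:
    def test_shape_is_channels_squared(self, rng):
        win = make_window(rng, n_channels=62, n_samples=250)
        assert ccv_frequency(win).values.shape == (62, 62)

    def test_composition_oracle(self, rng):
        win = make_window(rng, n_channels=4, n_samples=40)
        for width in (1, 3, 5):
            m = ccv_frequency(win, SmoothingKernel(width)).values
            spec = smooth_spectrum(channel_spectrum(win),
                                   SmoothingKernel(width))
            for i in range(4):
                for j in range(4):
                    expected = cov_oracle(list(spec.mag[i]), list(spec.mag[j]))
                    assert m[i, j] == pytest.approx(expected, rel=1e-9)

    def test_positive_semidefinite(self, rng):
        for _ in range(20):
            win = make_window(rng, n_channels=6, n_samples=32)
            m = ccv_frequency(win).values
            np.testing.assert_allclose(m, m.T, atol=1e-10 * np.abs(m).max())
            assert np.linalg.eigvalsh(m).min() >= -1e-8 * np.trace(m)

    def test_circular_shift_invariance_vs_time_sensitivity(self, rng):
        """Per-channel circular delays: frequency features unchanged, time
        features measurably different — the delay-elimination mechanism."""
        for _ in range(10):
            win = make_window(rng, n_channels=5, n_samples=64)
            shifts = rng.integers(1, 32, size=5)
            shifted = win.data.copy()
            for ch, s in enumerate(shifts):
                shifted[ch] = np.roll(win.data[ch], int(s))
            win2 = type(win)(data=shifted, fs=win.fs, label=win.label,
                             subject_id=win.subject_id,
                             session_id=win.session_id,
                             recording_index=0, window_index=0)
            f1, f2 = ccv_frequency(win).values, ccv_frequency(win2).values
            np.testing.assert_allclose(f1, f2, rtol=1e-9, atol=1e-9 * np.abs(f1).max())
            t1, t2 = ccv_time(win).values, ccv_time(win2).values
            assert np.abs(t1 - t2).max() > 1e-3 * np.abs(t1).max()


class TestStandardize:
    def test_zero_mean_unit_std(self, rng):
        win = make_window(rng, n_channels=5, n_samples=32)
        (out,) = standardize_features([ccv_time(win)])
        assert out.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.values.std() == pytest.approx(1.0, rel=1e-9)
        assert out.label == win.label and out.domain == "time"

    def test_constant_matrix_maps_to_zero(self, rng):
        win = make_window(rng, n_channels=3, n_samples=16)
        m = ccv_time(win)
        const = type(m)(values=np.full((3, 3), 4.0), domain=m.domain,
                        label=m.label, origin=m.origin)
        (out,) = standardize_features([const])
        np.testing.assert_array_equal(out.values, 0.0)

    def test_affine_invariance(self, rng):
        win = make_window(rng, n_channels=4, n_samples=32)
        m = ccv_time(win)
        scaled = type(m)(values=3.5 * m.values - 7.0, domain=m.domain,
                         label=m.label, origin=m.origin)
        a = standardize_features([m])[0].values
        b = standardize_features([scaled])[0].values
        np.testing.assert_allclose(a, b, atol=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_psd_property(self, seed):
        rng = np.random.default_rng(seed)
        win = make_window(rng, n_channels=4, n_samples=24)
        for mat in (ccv_time(win), ccv_frequency(win)):
            m = mat.values
            assert np.abs(m - m.T).max() <= 1e-10 * max(np.abs(m).max(), 1e-30)
            assert np.linalg.eigvalsh(m).min() >= -1e-8 * np.trace(m)


class TestSerialization:
    def test_feature_set_round_trip(self, rng, tmp_path):
        from imspeech.features import load_features, save_features
        wins = [make_window(rng, n_channels=4, n_samples=32, window_index=i)
                for i in range(3)]
        mats = [ccv_frequency(w, SmoothingKernel(3)) for w in wins]
        save_features(mats, tmp_path / "feats.h5", win_len=0.5,
                      split=["train", "train", "test"])
        back = load_features(tmp_path / "feats.h5")
        assert len(back) == 3
        for a, b in zip(mats, back):
            np.testing.assert_array_equal(a.values, b.values)
            assert a.label == b.label
            assert a.domain == b.domain
            assert a.kernel.width == b.kernel.width
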