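"""Spectral chain: bipolar derivation, filtering, per-epoch FFT (checked
against a brute-force DFT), normalization contract and artifact rejection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sleepspectra as ss

FS = 512.0
N = 2048  # samples per 4-s epoch


def brute_force_onesided_power(x):
    """O(n^2) DFT periodogram oracle: one-sided power per component,
    normalised so the sum equals the mean square of the signal."""
    n = x.size
    k = np.arange(n // 2 + 1)
    j = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, j) / n)
    comp = np.abs(basis @ x) ** 2 / n ** 2
    comp *= 2.0
    comp[0] /= 2.0
    if n % 2 == 0:
        comp[-1] /= 2.0
    return comp


def bin_onesided(comp, fs, n, lo=1, hi=56):
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return np.array([comp[(freqs > f - 1) & (freqs <= f)].sum()
                     for f in range(lo, hi + 1)])


class TestBipolar:
    def test_common_mode_cancels(self, rng):
        x = rng.standard_normal(1000)
        rec = ss.Recording(channels={"EEG_F": x.copy(), "EEG_P": x.copy()},
                           sampling_rate_hz=FS)
        assert np.all(ss.derive_bipolar(rec) == 0)

    def test_difference_recovers_signal(self, rng):
        s = rng.standard_normal(1000)
        rec = ss.Recording(channels={"EEG_F": s, "EEG_P": np.zeros(1000)},
                           sampling_rate_hz=FS)
        assert np.array_equal(ss.derive_bipolar(rec), s)

    def test_missing_channel_named(self, rng):
        rec = ss.Recording(channels={"EEG_F": rng.standard_normal(10)},
                           sampling_rate_hz=FS)
        with pytest.raises(KeyError, match="EEG_P"):
            ss.derive_bipolar(rec)

    def test_independent_components_power_adds(self, rng):
        common = rng.standard_normal(200_000)
        a = 2.0 * rng.standard_normal(200_000)
        b = 3.0 * rng.standard_normal(200_000)
        rec = ss.Recording(channels={"EEG_F": common + a, "EEG_P": common + b},
                           sampling_rate_hz=FS)
        var = ss.derive_bipolar(rec).var()
        assert var == pytest.approx(4.0 + 9.0, rel=0.05)


class TestFilters:
    def test_dc_removed(self):
        x = np.full(int(10 * FS), 5.0)
        y = ss.apply_filters(x, FS)
        assert abs(y.mean()) < 1e-3 * 5.0

    def test_10hz_preserved(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = ss.apply_filters(x, FS)
        mid = slice(int(FS), -int(FS))  # ignore edge transients
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.02)

    def test_60hz_attenuated(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)
        y = ss.apply_filters(x, FS)
        mid = slice(int(FS), -int(FS))
        assert np.abs(y[mid]).max() <= 0.1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ss.apply_filters(np.zeros(4096), 64.0,
                             ss.FilterSpec(highpass_hz=40.0))


class TestEpochPowerSpectrum:
    def test_pure_sinusoid_lands_in_its_bin(self):
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * 10.0 * t)  # on the 0.25-Hz FFT grid
        spec = ss.epoch_power_spectrum(x, FS, 4.0)
        assert spec.power[0, 9] == pytest.approx(0.5, rel=1e-9)
        others = np.delete(spec.power[0], 9)
        assert np.all(others < 1e-12)

    def test_zero_signal(self):
        spec = ss.epoch_power_spectrum(np.zeros(3 * N), FS, 4.0)
        assert np.all(spec.power == 0)
        assert spec.n_epochs == 3

    def test_non_integral_epochs_rejected(self):
        with pytest.raises(ValueError, match="100 samples"):
            ss.epoch_power_spectrum(np.zeros(N + 100), FS, 4.0)

    def test_matches_brute_force_dft(self, rng):
        x = rng.standard_normal(N)
        spec = ss.epoch_power_spectrum(x, FS, 4.0)
        oracle = bin_onesided(brute_force_onesided_power(x), FS, N)
        np.testing.assert_allclose(spec.power[0], oracle, rtol=1e-6)

    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(N)
        comp = brute_force_onesided_power(x)
        assert comp.sum() == pytest.approx(np.mean(x ** 2), rel=1e-6)
        spec = ss.epoch_power_spectrum(x, FS, 4.0)
        in_range = comp[(np.fft.rfftfreq(N, 1 / FS) > 0)
                        & (np.fft.rfftfreq(N, 1 / FS) <= 56)].sum()
        assert spec.power[0].sum() == pytest.approx(in_range, rel=1e-9)


class TestNormalize:
    def test_single_epoch_sums_to_100(self, rng):
        spec = ss.EpochSpectra(power=rng.random((1, 56)))
        out = ss.normalize(spec)
        assert out.power.sum() == pytest.approx(100.0, abs=1e-9)

    def test_two_epochs_totals(self):
        p = np.zeros((2, 56))
        p[0, 0], p[1, 0] = 1.0, 3.0
        out = ss.normalize(ss.EpochSpectra(power=p))
        assert out.power[0].sum() == pytest.approx(50.0)
        assert out.power[1].sum() == pytest.approx(150.0)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_mean_retained_total_is_100(self, seed):
        rng = np.random.default_rng(seed)
        spec = ss.EpochSpectra(power=rng.random((50, 56)),
                               retained=rng.random(50) > 0.3)
        out = ss.normalize(spec)
        assert out.power[out.retained].sum(axis=1).mean() == \
            pytest.approx(100.0, abs=1e-6)

    def test_idempotent_on_normalized(self, rng):
        spec = ss.normalize(ss.EpochSpectra(power=rng.random((20, 56))))
        again = ss.normalize(spec)
        np.testing.assert_allclose(again.power, spec.power, rtol=1e-12)
        assert again.norm_constant == pytest.approx(spec.norm_constant)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ss.normalize(ss.EpochSpectra(power=np.zeros((3, 56))))


class TestRejection:
    def _noisy_spectra(self, rng, n=500):
        return ss.EpochSpectra(power=rng.gamma(4.0, 1.0, size=(n, 56)))

    def test_clean_spectra_nothing_removed(self, rng):
        spec = self._noisy_spectra(rng)
        out, report = ss.reject_artifacts(spec, 300.0, 2)
        assert out.retained.all()
        assert (report["epochs_removed"] == 0).all()

    def test_spiked_epoch_removed_first_pass(self, rng):
        spec = self._noisy_spectra(rng)
        spec.power[17, 3] = spec.power.sum(axis=1).mean() * 30
        out, report = ss.reject_artifacts(spec, 300.0, 2)
        assert not out.retained[17]
        assert out.retained.sum() == spec.n_epochs - 1
        assert report.loc[0, "epochs_removed"] == 1

    def test_infinite_threshold_keeps_mask(self, rng):
        spec = self._noisy_spectra(rng)
        spec.retained[5] = False
        out, _ = ss.reject_artifacts(spec, np.inf, 2)
        assert np.array_equal(out.retained, spec.retained)

    def test_mean_total_100_after_each_pass(self, rng):
        spec = self._noisy_spectra(rng)
        spec.power[3, 2] = 1e4
        spec.power[11, 40] = 5e3
        out = spec
        for _ in range(3):
            out = ss.normalize(out)
            assert out.power[out.retained].sum(axis=1).mean() == \
                pytest.approx(100.0, abs=1e-6)
            exceed = (out.power > 300.0).any(axis=1)
            out.retained &= ~exceed

    def test_retained_sets_nested_over_passes(self, rng):
        spec = self._noisy_spectra(rng)
        spec.power[rng.integers(0, 500, 10), 5] += 400
        one, _ = ss.reject_artifacts(spec, 300.0, 1)
        two, _ = ss.reject_artifacts(spec, 300.0, 2)
        assert np.all(two.retained <= one.retained)

    def test_higher_threshold_removes_no_more(self, rng):
        spec = self._noisy_spectra(rng)
        spec.power[rng.integers(0, 500, 10), 5] += 300
        low, _ = ss.reject_artifacts(spec, 250.0, 2)
        high, _ = ss.reject_artifacts(spec, 400.0, 2)
        assert high.retained.sum() >= low.retained.sum()
        assert np.all(low.retained <= high.retained)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(20 * N) * 40.0
        x[3 * N + 100: 3 * N + 400] += 800.0 * np.sin(
            2 * np.pi * 2.0 * np.arange(300) / FS)
        a = ss.epoch_power_spectrum(x, FS, 4.0)
        b = ss.epoch_power_spectrum(7.5 * x, FS, 4.0)
        ca, _ = ss.reject_artifacts(a, 300.0, 2)
        cb, _ = ss.reject_artifacts(b, 300.0, 2)
        assert np.array_equal(ca.retained, cb.retained)
        np.testing.assert_allclose(ca.power, cb.power, rtol=1e-12)

    def test_all_epochs_removed_is_error(self):
        # identical epochs concentrated in one bin normalize to that bin
        # holding ~100% each; a 90% threshold then rejects every epoch
        power = np.zeros((4, 56))
        power[:, 2] = 1.0
        with pytest.raises(ValueError, match="removed all epochs"):
            ss.reject_artifacts(ss.EpochSpectra(power=power), 90.0, 1)
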