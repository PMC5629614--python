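import numpy as np
import pytest

import betamyg as bm
from betamyg.lfp import band_power, merge_windows, periodogram

RATE = 1871.0


def _sine(freq, duration=10.0, amp=1.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestDespike:
    def test_empty_spike_list_is_identity(self):
        lfp = bm.LFPRecording(_sine(10), rate=RATE)
        out = bm.despike(lfp, np.empty(0))
        assert np.array_equal(out.samples, lfp.samples)

    def test_artifact_removal_recovers_clean_sinusoid(self):
        """40 spike artifacts on a 10 Hz sinusoid: interpolated samples
        match the clean signal to <1% RMS of the amplitude."""
        rng = np.random.default_rng(0)
        clean = _sine(10, amp=100.0)
        spike_times = np.sort(rng.uniform(0.5, 9.5, 40))
        x = clean.copy()
        for t in spike_times:
            i = int(round(t * RATE))
            x[i - 1:i + 2] += 400.0  # ~1.6 ms transient centered on t
        out = bm.despike(bm.LFPRecording(x, rate=RATE), spike_times)
        err = out.samples - clean
        assert np.sqrt(np.mean(err ** 2)) < 1.0  # 1% of amplitude 100

    def test_samples_outside_windows_bitwise_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20000)
        spikes = np.array([2.0, 5.0, 5.001])
        out = bm.despike(bm.LFPRecording(x, rate=RATE), spikes)
        windows = merge_windows(np.column_stack([
            np.floor((spikes - 0.001) * RATE),
            np.ceil((spikes + 0.001) * RATE)]))
        mask = np.zeros(x.size, dtype=bool)
        for a, b in windows.astype(int):
            mask[a:b] = True
        assert np.array_equal(out.samples[~mask], x[~mask])

    def test_close_spikes_merge_into_one_window(self):
        assert len(merge_windows(np.array([[10.0, 14.0], [13.0, 18.0]]))) == 1
        assert len(merge_windows(np.array([[10.0, 14.0], [15.0, 18.0]]))) == 2


class TestRereference:
    def test_zero_reference_is_identity(self):
        lfp = bm.LFPRecording(_sine(10), rate=RATE)
        ref = bm.LFPRecording(np.zeros(lfp.n), rate=RATE)
        assert np.array_equal(bm.rereference(lfp, ref).samples, lfp.samples)

    def test_identical_channels_cancel(self):
        lfp = bm.LFPRecording(_sine(10), rate=RATE)
        assert np.allclose(bm.rereference(lfp, lfp).samples, 0.0)

    def test_common_mode_line_noise_attenuated_40db(self):
        rng = np.random.default_rng(2)
        common = _sine(60, amp=50.0)
        a = bm.LFPRecording(common + rng.standard_normal(common.size),
                            rate=RATE)
        b = bm.LFPRecording(common + rng.standard_normal(common.size),
                            rate=RATE)
        out = bm.rereference(a, b)
        p_in = band_power(a.samples, RATE, (59, 61))
        p_out = band_power(out.samples, RATE, (59, 61))
        assert 10 * np.log10(p_in / p_out) >= 40

    def test_rate_mismatch_fatal(self):
        a = bm.LFPRecording(np.zeros(100), rate=1871.0)
        b = bm.LFPRecording(np.zeros(100), rate=1000.0)
        with pytest.raises(ValueError, match="rate"):
            bm.rereference(a, b)


class TestBandpass:
    def test_passband_zero_phase(self):
        """22 Hz sinusoid through the 15-30 Hz filter: peak
        cross-correlation at zero lag (forward-backward filtering)."""
        x = _sine(22)
        out = bm.bandpass(bm.LFPRecording(x, rate=RATE), 15, 30)
        xc = np.correlate(out.samples[2000:-2000], x[2000:-2000], "full")
        lag = np.argmax(xc) - (len(x) - 4000 - 1)
        assert lag == 0

    def test_stopband_attenuation(self):
        x = _sine(5)
        out = bm.bandpass(bm.LFPRecording(x, rate=RATE), 15, 30)
        rms_ratio = np.std(out.samples) / np.std(x)
        assert rms_ratio < 0.05

    def test_dc_rejection(self):
        lfp = bm.LFPRecording(np.full(20000, 123.0), rate=RATE)
        assert abs(bm.bandpass(lfp, 15, 30).samples.mean()) < 1e-6

    def test_band_above_nyquist_fatal(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bm.bandpass(bm.LFPRecording(np.zeros(100), rate=100.0), 15, 60)

    def test_repeated_filtering_squares_magnitude_response(self):
        """Filtering twice attenuates a band-edge sinusoid by the same
        factor as the first pass (|H|² applied twice = |H|⁴)."""
        x = _sine(31.0)  # just outside the band
        lfp = bm.LFPRecording(x, rate=RATE)
        once = bm.bandpass(lfp, 15, 30)
        twice = bm.bandpass(once, 15, 30)
        mid = slice(4000, -4000)
        g1 = np.std(once.samples[mid]) / np.std(x[mid])
        g2 = np.std(twice.samples[mid]) / np.std(once.samples[mid])
        assert g1 == pytest.approx(g2, rel=0.02)


def test_parseval_total_power_equals_mean_square():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(4096)
    f, p = periodogram(x, RATE, window="boxcar")
    df = f[1] - f[0]
    assert p.sum() * df == pytest.approx(np.mean(x ** 2), rel=1e-6)


class TestTrialBandPower:
    @staticmethod
    def _trials(n, spacing=40.0, start=20.0):
        import pandas as pd
        cue = start + spacing * np.arange(n)
        return pd.DataFrame({"trial_index": np.arange(n), "cue_on_t": cue,
                             "release_t": cue + 7.0})

    def test_stationary_noise_mean_difference_near_zero(self):
        rng = np.random.default_rng(4)
        lfp = bm.LFPRecording(rng.standard_normal(int(RATE * 900)), rate=RATE)
        recs = bm.trial_band_power(lfp, self._trials(20), (15, 30))
        diffs = np.array([r.difference for r in recs])
        assert abs(diffs.mean()) < 2 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_post_only_sinusoid_difference_is_half_amp_squared(self):
        """A β sinusoid of amplitude A present only post-release raises
        the band-power difference by ~A²/2 (spectrum scaling)."""
        rng = np.random.default_rng(5)
        n = int(RATE * 900)
        x = 0.01 * rng.standard_normal(n)
        trials = self._trials(20)
        t = np.arange(n) / RATE
        amp = 2.0
        for rel in trials["release_t"]:
            sel = (t >= rel + 0.1) & (t < rel + 2.9)
            x[sel] += amp * np.sin(2 * np.pi * 22.0 * t[sel])
        recs = bm.trial_band_power(bm.LFPRecording(x, rate=RATE), trials,
                                   (15, 30))
        mean_diff = np.mean([r.difference for r in recs])
        assert mean_diff == pytest.approx(amp ** 2 / 2, rel=0.05)

    def test_trial_without_release_skipped(self):
        import pandas as pd
        trials = pd.DataFrame({"trial_index": [0, 1],
                               "cue_on_t": [20.0, 60.0],
                               "release_t": [27.0, np.nan]})
        lfp = bm.LFPRecording(np.random.default_rng(6).standard_normal(
            int(RATE * 100)), rate=RATE)
        recs = bm.trial_band_power(lfp, trials, (15, 30))
        assert [r.trial_index for r in recs] == [0]


class TestPeakFrequency:
    def test_injected_burst_peak_recovered(self):
        x = _sine(22, duration=4.0)
        spec = bm.window_spectrum(bm.LFPRecording(x, rate=RATE), 0.0, 4.0)
        freq, flat = bm.peak_frequency(spec, (15, 30))
        assert not flat
        assert freq == pytest.approx(22.0, abs=1.0 / 4.0)

    def test_flat_spectrum_flagged_lower_edge(self):
        spec = bm.PowerSpectrum(freqs=np.linspace(10, 40, 31),
                                power=np.ones(31))
        freq, flat = bm.peak_frequency(spec, (15, 30))
        assert flat and freq == 15.0

    def test_tie_breaks_toward_lower_frequency(self):
        freqs = np.linspace(10, 40, 31)
        power = np.zeros(31)
        power[freqs == 20.0] = 5.0
        power[freqs == 25.0] = 5.0
        freq, flat = bm.peak_frequency(bm.PowerSpectrum(freqs, power), (15, 30))
        assert freq == 20.0 and not flat


class TestNormalizeAcrossChannels:
    def test_arithmetic(self):
        np.testing.assert_array_equal(
            bm.normalize_across_channels([3.0, 5.0, 7.0]), [-2.0, 0.0, 2.0])

    def test_equal_powers_all_zero(self):
        assert np.all(bm.normalize_across_channels([4.0, 4.0, 4.0]) == 0)

    def test_output_sums_to_zero(self):
        v = np.random.default_rng(7).random(9)
        assert bm.normalize_across_channels(v).sum() == pytest.approx(0, abs=1e-12)

    def test_single_channel_fatal(self):
        with pytest.raises(ValueError):
            bm.normalize_across_channels([1.0])


class TestSpectrogram:
    def test_white_noise_zscored_rows_near_zero(self):
        rng = np.random.default_rng(8)
        lfp = bm.LFPRecording(rng.standard_normal(int(RATE * 300)), rate=RATE)
        f, rel, m = bm.spectrogram(lfp, [60.0, 120.0, 180.0], window=(-5, 10))
        assert np.abs(np.nanmean(m, axis=1)).mean() < 0.5

    def test_beta_band_elevated_after_press_in_old_session(self, analyzed,
                                                           high_burst_session):
        """Aligned on the lever press, the 15-30 Hz rows rise between
        press and press+3 s compared to the pre-press baseline."""
        _, bundle, _ = high_burst_session
        presses = bundle.events.times_of("lever_press")
        f, rel, m = bm.spectrogram(bundle.lfp, presses, window=(-5, 8))
        beta_rows = (f >= 15) & (f <= 30)
        post = m[np.ix_(beta_rows, (rel >= 0.0) & (rel < 3.0))].mean()
        pre = m[np.ix_(beta_rows, (rel >= -5.0) & (rel < -1.0))].mean()
        assert post > pre + 0.2
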