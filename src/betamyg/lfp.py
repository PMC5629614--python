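"""LFP preprocessing: de-spiking, re-referencing, zero-phase band
filtering, trial-aligned spectral power, and cross-channel power
normalization.

Spectral conventions. Per-window spectra are Hann-tapered
periodograms in density scaling (µV²/Hz); band power integrates the
density over the band (µV²), so a sinusoid of amplitude A contributes
A²/2 to the band containing it regardless of the taper. Only
differences and ratios of band power are used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .session import LFPRecording

logger = logging.getLogger(__name__)


@dataclass
class PowerSpectrum:
    """Single-window power spectrum (freqs Hz, power density µV²/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    window: tuple[float, float] | None = None


@dataclass
class BandPowerRecord:
    """Per-trial band power in the post-press and baseline windows."""

    trial_index: int
    band: tuple[float, float]
    post_power: float
    baseline_power: float

    @property
    def difference(self) -> float:
        return self.post_power - self.baseline_power


def merge_windows(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent half-open [a, b) intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2))
    iv = np.asarray(intervals, dtype=float)
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].copy()]
    for a, b in iv[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append(np.array([a, b]))
    return np.array(out)


def despike(lfp: LFPRecording, spike_times: np.ndarray,
            half_width: float = 0.001, n_anchor: int = 8) -> LFPRecording:
    """Remove spike transients by excision + cubic-spline interpolation.

    A ``[t - 1 ms, t + 1 ms)`` window around every spike time is
    excised (overlapping windows merged) and refilled with a cubic
    spline anchored on ``n_anchor`` intact samples on each side. All
    samples outside excision windows are returned bit-identical.
    Windows at the recording edge fall back to nearest-neighbor
    extension with a warning.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        return replace(lfp, samples=lfp.samples.copy())
    x = lfp.samples.copy()
    n = x.size
    lo = np.floor((spike_times - half_width - lfp.t0) * lfp.rate).astype(int)
    hi = np.ceil((spike_times + half_width - lfp.t0) * lfp.rate).astype(int)
    windows = merge_windows(np.column_stack([lo, hi]).astype(float)).astype(int)
    for a, b in windows:
        a_c, b_c = max(a, 0), min(b, n)
        if a_c >= b_c:
            continue
        left = np.arange(max(a_c - n_anchor, 0), a_c)
        right = np.arange(b_c, min(b_c + n_anchor, n))
        anchors = np.concatenate([left, right])
        if left.size == 0 or right.size == 0:
            if anchors.size == 0:
                continue
            logger.warning("spike window at recording edge: nearest-neighbor fill")
            x[a_c:b_c] = x[left[-1]] if left.size else x[right[0]]
            continue
        spline = CubicSpline(anchors, x[anchors])
        x[a_c:b_c] = spline(np.arange(a_c, b_c))
    return replace(lfp, samples=x)


def rereference(lfp: LFPRecording, reference: LFPRecording) -> LFPRecording:
    """Subtract a reference channel sample-wise (e.g. cerebellar screw)."""
    if lfp.rate != reference.rate:
        raise ValueError(f"rate mismatch: {lfp.rate} vs {reference.rate}")
    if lfp.n != reference.n:
        raise ValueError(f"length mismatch: {lfp.n} vs {reference.n}")
    return replace(lfp, samples=lfp.samples - reference.samples)


def bandpass(lfp: LFPRecording, lo: float, hi: float,
             order: int = 4) -> LFPRecording:
    """Zero-phase Butterworth bandpass.

    ``order`` is the effective magnitude order: a half-order filter is
    applied forward and backward (filtfilt), so the default 4 matches a
    fourth-order magnitude response with zero phase distortion.
    """
    nyq = lfp.rate / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
    if order % 2:
        raise ValueError("order must be even (applied half forward, half backward)")
    sos = signal.butter(order // 2, [lo, hi], btype="bandpass",
                        fs=lfp.rate, output="sos")
    return replace(lfp, samples=signal.sosfiltfilt(sos, lfp.samples))


def periodogram(x: np.ndarray, rate: float,
                window: str = "hann") -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram in density scaling (µV²/Hz).

    Density scaling makes band power (bins × bin width) independent of
    the taper's noise bandwidth: summed over all bins it equals the
    window-weighted mean square (exactly the time-domain mean square
    for a boxcar), and an amplitude-A sinusoid contributes A²/2 to any
    band containing it.
    """
    return signal.periodogram(np.asarray(x, float), fs=rate, window=window,
                              scaling="density", detrend=False)


def band_power(x: np.ndarray, rate: float, band: tuple[float, float],
               window: str = "hann") -> float:
    """Periodogram power integrated over the band (µV²)."""
    f, p = periodogram(x, rate, window=window)
    df = f[1] - f[0]
    sel = (f >= band[0]) & (f <= band[1])
    return float(p[sel].sum() * df)


def _slice(lfp: LFPRecording, start: float, end: float) -> np.ndarray | None:
    i0 = int(round((start - lfp.t0) * lfp.rate))
    i1 = int(round((end - lfp.t0) * lfp.rate))
    if i0 < 0 or i1 > lfp.n or i1 <= i0:
        return None
    return lfp.samples[i0:i1]


def trial_band_power(lfp: LFPRecording, trials, band: tuple[float, float],
                     post_window: tuple[float, float] = (0.1, 2.9),
                     baseline_window: tuple[float, float] = (-2.9, -0.1),
                     ) -> list[BandPowerRecord]:
    """Per-trial band power after the lever release vs the pre-cue baseline.

    ``post_window`` is relative to lever release (default 0.1–2.9 s
    after), ``baseline_window`` relative to cue onset (default 2.9–0.1 s
    before). Trials missing a release, or whose windows leave the
    recording, are skipped with a log entry.
    """
    records = []
    for row in trials.itertuples():
        if not np.isfinite(row.release_t) or not np.isfinite(row.cue_on_t):
            logger.info("trial %d: no lever release, skipped", row.trial_index)
            continue
        post = _slice(lfp, row.release_t + post_window[0],
                      row.release_t + post_window[1])
        base = _slice(lfp, row.cue_on_t + baseline_window[0],
                      row.cue_on_t + baseline_window[1])
        if post is None or base is None:
            logger.warning("trial %d: window outside recording, skipped",
                           row.trial_index)
            continue
        records.append(BandPowerRecord(
            trial_index=int(row.trial_index), band=band,
            post_power=band_power(post, lfp.rate, band),
            baseline_power=band_power(base, lfp.rate, band)))
    return records


def window_spectrum(lfp: LFPRecording, start: float, end: float,
                    window: str = "hann") -> PowerSpectrum:
    x = _slice(lfp, start, end)
    if x is None:
        raise ValueError(f"window [{start}, {end}) outside recording")
    f, p = periodogram(x, lfp.rate, window=window)
    return PowerSpectrum(freqs=f, power=p, window=(start, end))


def peak_frequency(spectrum: PowerSpectrum, band: tuple[float, float],
                   flat_rtol: float = 1e-9) -> tuple[float, bool]:
    """Frequency of maximum power within ``band``.

    Returns ``(freq, flat)``; ties break toward the lower frequency,
    and a flat in-band spectrum returns the lower band edge with
    ``flat=True``.
    """
    sel = (spectrum.freqs >= band[0]) & (spectrum.freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} outside spectrum range")
    f, p = spectrum.freqs[sel], spectrum.power[sel]
    span = p.max() - p.min()
    if span <= flat_rtol * max(p.max(), 1e-300):
        return float(f[0]), True
    return float(f[np.argmax(p)]), False


def normalize_across_channels(values) -> np.ndarray:
    """Subtract the across-channel mean (per-session tetrode normalization).

    Output sums to zero exactly; requires at least two channels.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("cross-channel normalization needs >= 2 channels")
    return v - v.mean(axis=0)


def spectrogram(lfp: LFPRecording, align_times,
                window: tuple[float, float] = (-5.0, 10.0),
                nperseg: int = 512, noverlap: int | None = None,
                normalization: str = "zscore",
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-aligned average spectrogram.

    Short-time spectra of the whole trace are computed once, columns
    within ``window`` of each alignment time are averaged across
    events, and each frequency row is z-scored against its session-wide
    distribution (``normalization='zscore'``; 'none' returns raw power).

    Returns ``(freqs, rel_times, matrix)`` with matrix shape
    ``(n_freqs, n_times)``.
    """
    if noverlap is None:
        noverlap = (3 * nperseg) // 4
    f, t, sxx = signal.spectrogram(lfp.samples, fs=lfp.rate, nperseg=nperseg,
                                   noverlap=noverlap, scaling="spectrum",
                                   window="hann")
    t = t + lfp.t0
    dt = t[1] - t[0] if t.size > 1 else 1.0
    n_bins = int(round((window[1] - window[0]) / dt))
    rel = window[0] + dt * np.arange(n_bins)
    acc = np.zeros((f.size, n_bins))
    count = 0
    for at in np.asarray(align_times, dtype=float):
        i0 = int(np.searchsorted(t, at + window[0]))
        if i0 + n_bins > t.size:
            continue
        acc += sxx[:, i0:i0 + n_bins]
        count += 1
    if count == 0:
        return f, rel, np.full((f.size, n_bins), np.nan)
    avg = acc / count
    if normalization == "zscore":
        mu = sxx.mean(axis=1, keepdims=True)
        sd = sxx.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        avg = (avg - mu) / sd
    return f, rel, avg
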