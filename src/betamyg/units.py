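"""Single-unit analysis: inclusion criteria, firing-pattern
classification, spike–β phase extraction, Rayleigh statistics, and
rate-modulation regression.

Classification uses three summaries of the spike train: the local
variation (LV) of interspike intervals — 0 for clock-like trains,
≈ 1 for Poisson — the slope of a line fitted to the normalized
single-sided autocorrelogram (500 ms span, 1 ms bins), and a
bimodality test on the smoothed log-ISI distribution. Precedence:
tonic if LV < 0.5; otherwise bursty if the log-ISI distribution is
bimodal; otherwise irregular if the AC slope is below −0.005/ms, else
irregular/bursty.

Phase convention: spike phases are taken from the Hilbert-transformed
β-filtered LFP, with 0° at the oscillation peak and increasing with
time (so a trough is 180°).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema, hilbert
import statsmodels.api as sm

from .events import BetaEvent
from .session import LFPRecording, SpikeTrain

logger = logging.getLogger(__name__)

CATEGORIES = ("tonic", "irregular", "irregular_bursty", "bursty", "unclassified")


@dataclass
class UnitClassification:
    unit_id: str
    included: bool
    lv: float | None
    ac_decay: float | None
    isi_bimodal: bool | None
    category: str
    reason: str = ""


@dataclass
class PhaseSample:
    """Spike phases (degrees, [0, 360)) of one unit inside β epochs."""

    unit_id: str
    phases: np.ndarray
    n_available: int

    @property
    def n(self) -> int:
        return self.phases.size


@dataclass
class RayleighResult:
    n: int
    r: float
    z: float
    p: float
    mean_angle: float  # degrees in [0, 360)


def unit_inclusion(train: SpikeTrain, refractory: float = 0.002,
                   max_violation: float = 0.003,
                   min_rest_rate: float = 0.01) -> tuple[bool, str]:
    """Unit quality gate.

    Included iff the fraction of ISIs shorter than the 2 ms refractory
    period is below 0.3 % and the firing rate during the pre-task rest
    window is at least 0.01 Hz.
    """
    if train.n < 2:
        return False, "fewer than 2 spikes"
    isis = train.isis()
    frac = float((isis < refractory).mean())
    if frac >= max_violation:
        return False, f"refractory violations {frac:.4f} >= {max_violation}"
    r0, r1 = train.rest_window
    rest_dur = r1 - r0
    if rest_dur <= 0:
        return False, "empty rest window"
    rest_rate = np.sum((train.times >= r0) & (train.times < r1)) / rest_dur
    if rest_rate < min_rest_rate:
        return False, f"rest rate {rest_rate:.4f} Hz < {min_rest_rate}"
    return True, ""


def local_variance(isis) -> float:
    """Local variation LV of consecutive ISIs.

    LV = 3/(n−1) · Σ ((Iᵢ − Iᵢ₊₁)/(Iᵢ + Iᵢ₊₁))² over the n−1 adjacent
    ISI pairs. 0 for a perfectly regular train, ≈ 1 for Poisson.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        raise ValueError("LV needs at least two ISIs")
    if np.any(isis <= 0):
        raise ValueError("nonpositive ISI")
    ratio = (isis[:-1] - isis[1:]) / (isis[:-1] + isis[1:])
    return float(3.0 * np.mean(ratio ** 2))


def autocorrelogram(times: np.ndarray, span: float = 0.5,
                    bin_width: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """Normalized single-sided spike-train autocorrelogram.

    Counts of spike-pair lags in (0, span], binned at ``bin_width`` and
    normalized to unit mean, so a Poisson train is flat at 1.
    """
    times = np.asarray(times, dtype=float)
    lags = []
    j0 = 0
    for i, t in enumerate(times):
        j = np.searchsorted(times, t + span, side="right")
        d = times[i + 1:j] - t
        if d.size:
            lags.append(d)
    edges = np.arange(0.0, span + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.concatenate(lags) if lags else [], bins=edges)
    counts = counts.astype(float)
    m = counts.mean()
    if m > 0:
        counts /= m
    centers = edges[:-1] + bin_width / 2
    return centers, counts


def ac_decay_rate(train: SpikeTrain, span: float = 0.5,
                  bin_width: float = 0.001,
                  min_spikes: int = 100) -> float | None:
    """Slope (per ms) of a least-squares line on the normalized AC.

    Returns None (undefined) when the train has too few spikes for a
    stable autocorrelogram.
    """
    if train.n < min_spikes:
        logger.info("unit %s: %d spikes, AC decay undefined",
                    train.unit_id, train.n)
        return None
    centers, ac = autocorrelogram(train.times, span=span, bin_width=bin_width)
    ms = centers * 1000.0
    slope = np.polyfit(ms, ac, 1)[0]
    return float(slope)


def isi_bimodality(train: SpikeTrain, min_isis: int = 50, n_bins: int = 60,
                   sigma_bins: float = 2.0, peak_ratio: float = 0.10,
                   valley_ratio: float = 0.50) -> bool | None:
    """Bimodality of the smoothed log₁₀-ISI distribution.

    Bimodal iff the smoothed histogram has ≥ 2 local maxima whose
    smaller peak is at least ``peak_ratio`` of the larger and the
    deepest valley between them is below ``valley_ratio`` of the
    smaller peak. Returns None when fewer than ``min_isis`` ISIs exist
    or the ISIs are degenerate.
    """
    isis = train.isis()
    isis = isis[isis > 0]
    if isis.size < min_isis:
        return None
    log_isi = np.log10(isis)
    lo, hi = log_isi.min() - 0.2, log_isi.max() + 0.2
    if hi - lo < 1e-9:
        return None
    hist, edges = np.histogram(log_isi, bins=n_bins, range=(lo, hi))
    smooth = gaussian_filter1d(hist.astype(float), sigma=sigma_bins)
    maxima = argrelextrema(smooth, np.greater_equal, order=2)[0]
    # deduplicate plateaus
    maxima = [m for k, m in enumerate(maxima)
              if k == 0 or m - maxima[k - 1] > 2]
    peaks = sorted(((smooth[m], m) for m in maxima), reverse=True)
    if len(peaks) < 2:
        return False
    (h1, i1), (h2, i2) = peaks[0], peaks[1]
    if h2 < peak_ratio * h1:
        return False
    a, b = sorted((i1, i2))
    valley = smooth[a:b + 1].min()
    return bool(valley < valley_ratio * h2)


def classify_unit(lv: float | None, ac_decay: float | None,
                  isi_bimodal: bool | None,
                  lv_tonic: float = 0.5,
                  ac_threshold: float = -0.005) -> str:
    """Firing-pattern category from the three train summaries.

    Precedence: tonic (LV < 0.5) → bursty (bimodal log-ISI) →
    irregular (AC slope strictly below −0.005/ms) → irregular_bursty.
    Undefined inputs that are needed to decide yield 'unclassified'.
    """
    if lv is None:
        return "unclassified"
    if lv < lv_tonic:
        return "tonic"
    if isi_bimodal is None:
        return "unclassified"
    if isi_bimodal:
        return "bursty"
    if ac_decay is None:
        return "unclassified"
    return "irregular" if ac_decay < ac_threshold else "irregular_bursty"


def classify_train(train: SpikeTrain) -> UnitClassification:
    """Run inclusion and the full classification cascade on one unit."""
    included, reason = unit_inclusion(train)
    lv = None
    if train.n >= 3:
        isis = train.isis()
        if np.all(isis > 0):
            lv = local_variance(isis)
    ac = ac_decay_rate(train)
    bimodal = isi_bimodality(train)
    return UnitClassification(unit_id=train.unit_id, included=included,
                              lv=lv, ac_decay=ac, isi_bimodal=bimodal,
                              category=classify_unit(lv, ac, bimodal),
                              reason=reason)


def instantaneous_phase_deg(beta_lfp: LFPRecording) -> np.ndarray:
    """Phase of the analytic (Hilbert) signal in degrees, 0° = peak."""
    analytic = hilbert(beta_lfp.samples)
    return np.degrees(np.angle(analytic)) % 360.0


def spike_beta_phases(train: SpikeTrain, beta_lfp: LFPRecording,
                      events: list[BetaEvent], n_sub: int = 50,
                      seed: int = 0) -> PhaseSample | None:
    """β phase of each spike inside detected β epochs, subsampled to 50.

    Spikes outside every event are discarded. If at least ``n_sub``
    remain, exactly ``n_sub`` are drawn without replacement (seeded);
    otherwise the unit is excluded from coherence analysis (None).
    """
    if not events:
        return None
    phase = instantaneous_phase_deg(beta_lfp)
    t = train.times
    mask = np.zeros(t.size, dtype=bool)
    for ev in events:
        mask |= (t >= ev.onset) & (t < ev.offset)
    in_epoch = t[mask]
    n_avail = in_epoch.size
    if n_avail < n_sub:
        logger.info("unit %s: only %d in-epoch spikes (<%d), excluded",
                    train.unit_id, n_avail, n_sub)
        return None
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n_avail, size=n_sub, replace=False))
    idx = beta_lfp.index_of(in_epoch[chosen])
    return PhaseSample(unit_id=train.unit_id, phases=phase[idx],
                       n_available=n_avail)


def rayleigh_test(phases_deg) -> RayleighResult:
    """Rayleigh test of circular uniformity with exponential p-approximation.

    r is the mean resultant length, z = n·r², and
    p ≈ exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)) with R = n·r,
    clamped to (0, 1] (the approximation can exceed 1 for tiny r).
    """
    phases = np.radians(np.asarray(phases_deg, dtype=float))
    n = phases.size
    if n < 1:
        raise ValueError("need at least one phase")
    c, s = np.cos(phases).mean(), np.sin(phases).mean()
    r = float(np.hypot(c, s))
    r = min(r, 1.0)
    z = n * r ** 2
    big_r = n * r
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n ** 2 - big_r ** 2))
                     - (1.0 + 2.0 * n)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    mean_angle = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return RayleighResult(n=n, r=r, z=float(z), p=p, mean_angle=mean_angle)


def rate_modulation(counts, beta_present, covariates=None,
                    min_per_class: int = 10) -> dict | None:
    """Robust regression of per-trial firing counts on β presence.

    Iteratively reweighted least squares with a Tukey bisquare loss
    (the robust multilinear regression of the original analysis);
    returns the β-presence coefficient, its SE and p-value, or None
    for degenerate designs (fewer than ``min_per_class`` trials in
    either class, or zero-variance counts).
    """
    y = np.asarray(counts, dtype=float)
    flag = np.asarray(beta_present, dtype=float)
    n0, n1 = int((flag == 0).sum()), int((flag == 1).sum())
    if n0 < min_per_class or n1 < min_per_class:
        logger.info("rate modulation skipped: class sizes %d/%d", n0, n1)
        return None
    if np.ptp(y) == 0:
        logger.info("rate modulation skipped: zero-variance counts")
        return None
    cols = [flag]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == y.size:
            cols.extend(cov.T)
        else:
            cols.extend(cov)
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
    coef, se = float(fit.params[1]), float(fit.bse[1])
    pval = float(fit.pvalues[1])
    return {"coef": coef, "se": se, "p": pval}
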