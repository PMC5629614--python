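"""β-event detection and task alignment.

A β event is a sustained epoch of elevated band power: the de-spiked
LFP is bandpass filtered (20–40 Hz by default), squared, envelope-
smoothed with a 100 ms moving average (an unsmoothed squared
oscillation crosses zero twice per cycle and could never stay above
threshold for 350 ms), and thresholded at mean + 2 SD of the smoothed
squared signal over the whole recording. Maximal supra-threshold runs
lasting at least 350 ms become events; brief sub-threshold dips
(≤ 25 ms) are bridged so a single event is never split by one noisy
sample. Candidates dominated by amplifier clipping (a run of samples
pinned at the session's absolute maximum) are rejected automatically
and logged.

Because the threshold is defined relative to the signal's own mean and
SD, the detector is invariant to any positive gain applied to the LFP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d, gaussian_filter1d

from .lfp import bandpass
from .session import LFPRecording

logger = logging.getLogger(__name__)

#: band used for event extraction (the spectral-analysis band preset
#: is 15–30 Hz; event identification uses 20–40 Hz)
DETECTION_BAND = (20.0, 40.0)
SPECTRAL_BAND = (15.0, 30.0)


@dataclass
class BetaEvent:
    """One detected supra-threshold β epoch."""

    onset: float
    offset: float
    peak_squared_power: float
    trial_index: int | None = None
    task_evoked: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _runs(mask: np.ndarray) -> np.ndarray:
    """(start, end) index pairs of maximal True runs, end exclusive."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.column_stack([starts, ends])


def _bridge(mask: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill False gaps of at most ``max_gap`` samples between True runs."""
    if max_gap <= 0 or not mask.any():
        return mask
    out = mask.copy()
    gaps = _runs(~mask)
    for a, b in gaps:
        if a == 0 or b == mask.size:
            continue  # leading/trailing gaps are not between runs
        if b - a <= max_gap:
            out[a:b] = True
    return out


def threshold_runs(env: np.ndarray, rate: float, thr: float,
                   min_dur: float = 0.350, bridge: float = 0.025) -> np.ndarray:
    """Supra-threshold runs of an envelope, as (start, end) sample pairs.

    Maximal runs of ``env > thr`` with sub-threshold dips of at most
    ``bridge`` seconds bridged; runs shorter than ``min_dur`` (run
    length / rate, boundary inclusive: exactly ``min_dur`` is kept)
    are discarded.
    """
    above = _bridge(env > thr, int(round(bridge * rate)))
    runs = _runs(above)
    if runs.size == 0:
        return runs
    keep = (runs[:, 1] - runs[:, 0]) / rate >= min_dur
    return runs[keep]


def smoothed_squared_power(lfp: LFPRecording, band=DETECTION_BAND,
                           smooth: float = 0.100, order: int = 4) -> np.ndarray:
    """Band-filter, square, and moving-average the LFP (the detector input)."""
    filt = bandpass(lfp, band[0], band[1], order=order)
    sq = filt.samples ** 2
    width = max(int(round(smooth * lfp.rate)), 1)
    return uniform_filter1d(sq, size=width, mode="nearest")


def detect_beta_events(lfp: LFPRecording, band=DETECTION_BAND,
                       k_sd: float = 2.0, min_dur: float = 0.350,
                       smooth: float = 0.100, bridge: float = 0.025,
                       clip_frac: float = 0.995, clip_len: int = 5,
                       ) -> list[BetaEvent]:
    """Detect β events by the threshold-duration rule.

    Parameters mirror the operational definition: threshold at
    ``mean + k_sd · SD`` of the smoothed squared band signal computed
    over the entire recording, minimum duration ``min_dur`` (inclusive:
    a run lasting exactly 350 ms is accepted). Candidates containing
    ``clip_len`` consecutive samples at ≥ ``clip_frac`` of the session's
    absolute maximum are treated as clipping artifacts and dropped.
    """
    if lfp.duration < min_dur:
        warnings.warn("recording shorter than the minimum event duration")
        return []
    env = smoothed_squared_power(lfp, band=band, smooth=smooth)
    thr = env.mean() + k_sd * env.std()
    abs_max = np.abs(lfp.samples).max()
    events: list[BetaEvent] = []
    for a, b in threshold_runs(env, lfp.rate, thr, min_dur=min_dur,
                               bridge=bridge):
        seg = np.abs(lfp.samples[a:b])
        if abs_max > 0:
            clipped = seg >= clip_frac * abs_max
            if clipped.any():
                lengths = np.diff(_runs(clipped), axis=1)
                if lengths.size and lengths.max() >= clip_len:
                    logger.warning(
                        "candidate at %.3f s rejected as clipping artifact",
                        lfp.t0 + a / lfp.rate)
                    continue
        events.append(BetaEvent(onset=lfp.t0 + a / lfp.rate,
                                offset=lfp.t0 + b / lfp.rate,
                                peak_squared_power=float(env[a:b].max())))
    assert all(e0.offset <= e1.onset for e0, e1 in zip(events, events[1:])), \
        "detected events must be disjoint and sorted"
    return events


def classify_task_evoked(events: list[BetaEvent], trials,
                         window: float = 3.0) -> list[BetaEvent]:
    """Flag events whose onset falls within ``[press, press + window)``
    of some trial's lever press, and link them to that trial (in place)."""
    presses = trials[["trial_index", "press_t"]].dropna()
    for ev in events:
        ev.task_evoked = False
        ev.trial_index = None
        for row in presses.itertuples():
            if row.press_t <= ev.onset < row.press_t + window:
                ev.task_evoked = True
                ev.trial_index = int(row.trial_index)
                break
    return events


@dataclass
class IncidenceRecord:
    """Task-evoked β events per trial for one session-day."""

    session_id: str
    day: int
    task: str
    age_group: str
    n_task_evoked_events: int
    n_trials: int

    @property
    def incidence(self) -> float:
        return self.n_task_evoked_events / self.n_trials


def beta_incidence(events: list[BetaEvent], trials, meta: dict | None = None
                   ) -> IncidenceRecord:
    """Number of task-evoked β events divided by the number of trials."""
    n_trials = len(trials)
    if n_trials == 0:
        raise ValueError("incidence undefined for zero trials")
    meta = meta or {}
    return IncidenceRecord(
        session_id=str(meta.get("subject_id", "?")),
        day=int(meta.get("day", 0)), task=str(meta.get("task", "?")),
        age_group=str(meta.get("age_group", "?")),
        n_task_evoked_events=sum(e.task_evoked for e in events),
        n_trials=n_trials)


def align_event_times(events: list[BetaEvent], reference_times,
                      window: tuple[float, float] = (-2.0, 2.0),
                      bin_width: float = 0.05, density_sigma_bins: float = 2.0,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of event onsets relative to the nearest reference event.

    Each event onset is assigned its offset from the nearest reference
    time (e.g. nose pokes or lever releases); offsets outside
    ``window`` are dropped. Returns ``(bin_edges, histogram, density)``
    where the histogram sums to 1 over retained events and the density
    is a Gaussian-smoothed version of it (per-second units).
    """
    refs = np.sort(np.asarray(reference_times, dtype=float))
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    if refs.size == 0 or not events:
        z = np.zeros(edges.size - 1)
        return edges, z, z
    onsets = np.array([e.onset for e in events])
    idx = np.clip(np.searchsorted(refs, onsets), 1, refs.size - 1)
    nearest = np.where(np.abs(onsets - refs[idx - 1])
                       <= np.abs(onsets - refs[idx]),
                       refs[idx - 1], refs[idx])
    offsets = onsets - nearest
    offsets = offsets[(offsets >= window[0]) & (offsets < window[1])]
    hist, _ = np.histogram(offsets, bins=edges)
    total = hist.sum()
    if total == 0:
        z = np.zeros(edges.size - 1)
        return edges, z, z
    prob = hist / total
    density = gaussian_filter1d(prob, sigma=density_sigma_bins) / bin_width
    return edges, prob, density
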