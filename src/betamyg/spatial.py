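"""Spatial analysis: position cleaning, reward-zone occupancy,
occupancy-normalized β-power maps, and movement speed at β onsets.

The camera frame is divided into a 24 × 30 grid of 20 × 20 px bins
(0.2 cm/px, so each bin is 4 × 4 cm). Occupancy maps accumulate time
per bin; β-power maps are the per-bin power histogram divided by
occupancy, which makes them exactly invariant to how long the animal
dwelt in a bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .events import BetaEvent
from .session import PositionTrack

logger = logging.getLogger(__name__)

GRID_SHAPE = (24, 30)   # x bins, y bins
BIN_PX = 20.0


class SessionRejected(RuntimeError):
    """The session fails a data-quality gate (e.g. too many invalid
    position samples) and must be excluded from spatial analyses."""


@dataclass
class OccupancyMap:
    grid: np.ndarray              # seconds per bin, shape GRID_SHAPE
    bin_px: float = BIN_PX

    @property
    def total_time(self) -> float:
        return float(self.grid.sum())


@dataclass
class BetaPowerMap:
    grid: np.ndarray              # occupancy-normalized power
    mask: np.ndarray              # True where never visited


def clean_track(track: PositionTrack, max_invalid: float = 0.40,
                smooth: float = 0.5) -> PositionTrack:
    """Interpolate invalid samples and smooth the trajectory.

    Sessions with more than 40 % invalid timestamps are rejected
    (raises :class:`SessionRejected`). Invalid samples are filled by a
    cubic spline over valid samples (nearest-valid extension at the
    edges, with a warning), then x and y are each convolved with a
    unit-sum 500 ms Hamming window, which preserves constants.
    """
    if track.n == 0:
        raise SessionRejected("empty position track")
    frac = track.invalid_fraction
    if frac > max_invalid:
        raise SessionRejected(
            f"invalid position fraction {frac:.2f} > {max_invalid:.2f}")
    t, valid = track.times, track.valid
    x, y = track.x.copy(), track.y.copy()
    if not valid.all():
        tv = t[valid]
        if valid.sum() < 4:
            raise SessionRejected("too few valid position samples to interpolate")
        for arr in (x, y):
            spline = CubicSpline(tv, arr[valid])
            inside = (~valid) & (t >= tv[0]) & (t <= tv[-1])
            arr[inside] = spline(t[inside])
            lead, trail = (~valid) & (t < tv[0]), (~valid) & (t > tv[-1])
            if lead.any() or trail.any():
                logger.warning("leading/trailing invalid samples: "
                               "nearest-valid extension")
                arr[lead] = arr[valid][0]
                arr[trail] = arr[valid][-1]
    rate = 1.0 / np.median(np.diff(t)) if track.n > 1 else 60.0
    w = np.hamming(max(int(round(smooth * rate)), 1))
    w /= w.sum()
    pad = w.size // 2
    for arr_name in ("x", "y"):
        arr = x if arr_name == "x" else y
        padded = np.pad(arr, pad, mode="edge")
        sm = np.convolve(padded, w, mode="same")[pad:pad + arr.size]
        if arr_name == "x":
            x = sm
        else:
            y = sm
    return PositionTrack(t, x, y, np.ones(track.n, dtype=bool),
                         cm_per_px=track.cm_per_px)


def in_rectangle(x, y, rect) -> np.ndarray:
    """Membership in a half-open pixel rectangle (x0, y0, width, height)."""
    x0, y0, w, h = rect
    return (x >= x0) & (x < x0 + w) & (y >= y0) & (y < y0 + h)


def reward_zone_occupancy(track: PositionTrack, zone, trials) -> float:
    """Fraction of trial time spent inside the reward-zone rectangle.

    Only trials with a valid lever press contribute; each such trial
    spans ``[cue_on, cue_on + 40 s)``. ``zone`` is a pixel rectangle
    (x0, y0, w, h); the physical default is 10 × 20 cm in front of the
    feeder (50 × 100 px at 0.2 cm/px).
    """
    pressed = trials.dropna(subset=["press_t", "cue_on_t"])
    if len(pressed) == 0:
        raise SessionRejected("no trials with a valid lever press")
    sel = np.zeros(track.n, dtype=bool)
    for row in pressed.itertuples():
        sel |= (track.times >= row.cue_on_t) & (track.times < row.cue_on_t + 40.0)
    if not sel.any():
        raise SessionRejected("no position samples within trials")
    inside = in_rectangle(track.x[sel], track.y[sel], zone)
    return float(inside.mean())


def occupancy_map(track: PositionTrack, grid_shape=GRID_SHAPE,
                  bin_px: float = BIN_PX) -> OccupancyMap:
    """Time spent (s) per spatial bin of the camera frame."""
    dt = np.median(np.diff(track.times)) if track.n > 1 else 0.0
    edges_x = np.arange(grid_shape[0] + 1) * bin_px
    edges_y = np.arange(grid_shape[1] + 1) * bin_px
    counts, _, _ = np.histogram2d(track.x, track.y, bins=[edges_x, edges_y])
    return OccupancyMap(grid=counts * dt, bin_px=bin_px)


def subsample_power(power: np.ndarray, power_times: np.ndarray,
                    track_times: np.ndarray) -> np.ndarray:
    """Resample an LFP-rate power series at the position timestamps."""
    return np.interp(track_times, power_times, power)


def beta_power_heatmap(track: PositionTrack, power: np.ndarray,
                       grid_shape=GRID_SHAPE, bin_px: float = BIN_PX,
                       ) -> BetaPowerMap:
    """Occupancy-normalized spatial map of β power.

    ``power`` must be aligned to ``track.times`` (use
    :func:`subsample_power`). Each bin holds the mean power over the
    samples recorded there (the power-weighted histogram divided by
    the sample-count histogram); bins never visited are masked (NaN).
    """
    power = np.asarray(power, dtype=float)
    if power.size != track.n:
        raise ValueError("power series not aligned to track timestamps")
    edges_x = np.arange(grid_shape[0] + 1) * bin_px
    edges_y = np.arange(grid_shape[1] + 1) * bin_px
    counts, _, _ = np.histogram2d(track.x, track.y, bins=[edges_x, edges_y])
    psum, _, _ = np.histogram2d(track.x, track.y, bins=[edges_x, edges_y],
                                weights=power)
    mask = counts == 0
    if mask.all():
        logger.warning("β-power map has no visited bins")
    grid = np.full(counts.shape, np.nan)
    grid[~mask] = psum[~mask] / counts[~mask]
    return BetaPowerMap(grid=grid, mask=mask)


def beta_onset_locations(events: list[BetaEvent], track: PositionTrack
                         ) -> list[tuple[float, float, bool]]:
    """Head position at the start of each β event.

    Uses the nearest track timestamp at or before the onset; events
    starting outside the track span are skipped with a log entry.
    """
    out = []
    for ev in events:
        if ev.onset < track.times[0] or ev.onset > track.times[-1]:
            logger.warning("event onset %.2f s outside track span, skipped",
                           ev.onset)
            continue
        i = int(np.searchsorted(track.times, ev.onset, side="right")) - 1
        out.append((float(track.x[i]), float(track.y[i]), bool(ev.task_evoked)))
    return out


def _speed_at(track: PositionTrack, t0: float, window: float) -> float | None:
    """Net displacement speed over [t0, t0 + window), cm/s."""
    t1 = t0 + window
    if t0 < track.times[0] or t1 > track.times[-1]:
        return None
    x0 = np.interp(t0, track.times, track.x)
    y0 = np.interp(t0, track.times, track.y)
    x1 = np.interp(t1, track.times, track.x)
    y1 = np.interp(t1, track.times, track.y)
    dist_px = float(np.hypot(x1 - x0, y1 - y0))
    return dist_px * track.cm_per_px / window


def movement_velocity(track: PositionTrack, onset_times,
                      window: float = 0.5, baseline_ref=None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Movement speed over 0.5 s following each β onset, vs baseline.

    Speed is the net Euclidean displacement over ``[t, t + window)``
    divided by the window, in cm/s. Baselines use ``[t − window, t)``
    before each reference time (cue onsets). Events or baselines with
    insufficient track coverage are skipped.
    """
    speeds = [s for t in np.asarray(onset_times, dtype=float)
              if (s := _speed_at(track, t, window)) is not None]
    baselines = []
    if baseline_ref is not None:
        baselines = [s for t in np.asarray(baseline_ref, dtype=float)
                     if (s := _speed_at(track, t - window, window)) is not None]
    return np.asarray(speeds), np.asarray(baselines)
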