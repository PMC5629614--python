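"""Synthetic session generator with known ground truth.

Builds complete sessions — task event log, LFP with injected β bursts,
spike trains with controlled phase locking, and a goal-directed
position track — so every analysis stage can be tested against a
ground truth that real recordings never provide.

The task timing reproduces the operant trial cycle exactly: a 2 s cue
light, levers extended 3 s after cue offset, outcome delivered 3 s
after the lever press, and a fixed 40 s cue-onset period. Reward
magnitude and lever-training sessions run 5 blocks of 8 forced + 6
free-choice trials (70 trials); probability discounting and
discrimination sessions run blocks of 16 forced + 10 free (130
trials).

The LFP model is 1/f-shaped Gaussian background noise plus a slowly
amplitude-modulated theta sinusoid, with Tukey-tapered β bursts
injected at nose-poke (+ latency jitter) on a per-trial coin flip
whose probability depends on age group, plus optional spontaneous
bursts. Burst amplitude is parameterized in multiples of the
background SD, so detector tests are independent of absolute gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import (EventLog, LFPRecording, PositionTrack, SessionBundle,
                      SpikeTrain, EVENT_COLUMNS)

#: forced/free trial counts per block for each task
BLOCK_STRUCTURE = {
    "reward_magnitude": (8, 6),
    "lever_training": (8, 6),
    "prob_discounting": (16, 10),
    "prob_discrimination": (16, 10),
}


@dataclass
class UnitSpec:
    """Ground-truth parameters of one simulated unit."""

    unit_id: str
    pattern: str            # tonic | irregular | bursty
    rate: float             # baseline firing rate, Hz
    phase_locked: bool = False
    kappa: float = 0.0      # von Mises concentration inside β bursts
    mu_deg: float = 0.0     # preferred phase, degrees (0° = β peak)
    burst_rate_hz: float = 60.0  # in-burst firing rate for locked units


@dataclass
class SimConfig:
    """All knobs of the session simulator (defaults = study conditions)."""

    task: str = "reward_magnitude"
    age_group: str = "old"
    subject_id: str = "rat0"
    day: int = 1
    phase: str = "late"
    n_blocks: int = 5

    # trial timing (s)
    cue_dur: float = 2.0
    cue_to_lever: float = 3.0      # cue offset -> lever extension
    press_to_outcome: float = 3.0
    trial_period: float = 40.0     # cue-on to next cue-on
    response_window: float = 20.0
    press_latency: tuple[float, float] = (0.8, 5.0)   # uniform, after levers
    hold_dur: tuple[float, float] = (0.2, 0.5)        # press -> release
    #: reaction time (lever release -> nose poke at the food cup),
    #: lognormal median/sigma; the animal reaches the cup well before
    #: the outcome lands 3 s after the press, then waits there
    rt_median: float = 0.8
    rt_sigma: float = 0.35
    omission_prob: float = 0.0
    rest_dur: float = 60.0         # pre-task rest before first cue

    # choice policy / outcome schedule
    win_stay: float = 0.8
    lose_shift: float = 0.6
    #: per-lever reward probability; None -> task default (certain rewards
    #: for the magnitude/training tasks, risky large lever for the
    #: probability tasks)
    p_win: dict | None = None

    # LFP background
    lfp_rate: float = 1871.0
    noise_exponent: float = 1.0
    noise_sd: float = 50.0         # µV
    theta_freq: float = 7.5        # Hz (6-10)
    theta_amp: float = 25.0        # µV
    theta_mod_freq: float = 0.1    # Hz, slow amplitude modulation
    theta_mod_depth: float = 0.4

    # β bursts
    beta_freq: float = 22.0        # Hz, within the 19.2-25.6 Hz peak range
    beta_amp_sd: float = 4.0       # amplitude in multiples of background SD
    beta_dur: float = 0.5          # s
    beta_taper: float = 0.25       # Tukey taper fraction (1.0 = full Hann)
    beta_latency_mean: float = 0.1   # s after nose poke
    beta_latency_sd: float = 0.15
    burst_prob: dict = field(default_factory=lambda: {"old": 0.22, "young": 0.05})
    spontaneous_rate: float = 0.0  # Hz, bursts unrelated to task events

    # units
    units: list[UnitSpec] = field(default_factory=lambda: [
        UnitSpec("u00", "tonic", 6.0),
        UnitSpec("u01", "tonic", 4.0, phase_locked=True, kappa=4.0, mu_deg=18.0),
        UnitSpec("u02", "irregular", 5.0),
        UnitSpec("u03", "irregular", 5.0, phase_locked=True, kappa=4.0, mu_deg=18.0),
        UnitSpec("u04", "bursty", 4.0),
    ])

    # chamber geometry, camera pixels (0.2 cm/px; 480 x 600 px frame)
    cm_per_px: float = 0.2
    frame_px: tuple[int, int] = (480, 600)
    chamber_vertices: tuple = ((60, 40), (420, 40), (320, 560), (160, 560))
    feeder_px: tuple[float, float] = (240.0, 545.0)
    # 10 x 20 cm = 50 x 100 px rectangle in front of the feeder
    reward_zone_px: tuple[float, float, float, float] = (215.0, 445.0, 50.0, 100.0)
    lever_px: dict = field(default_factory=lambda: {"small": (110.0, 90.0),
                                                    "large": (370.0, 90.0)})
    pos_rate: float = 60.0
    pos_jitter_px: float = 1.5
    invalid_fraction: float = 0.05

    #: absolute refractory period imposed on every generated train (s);
    #: well-isolated units have essentially no sub-2 ms intervals
    spike_refractory: float = 0.0025

    seed: int = 0

    def reward_schedule(self) -> dict:
        if self.p_win is not None:
            return self.p_win
        if self.task in ("prob_discounting", "prob_discrimination"):
            return {"small": 1.0, "large": 0.5}
        return {"small": 1.0, "large": 1.0}

    def validate(self) -> None:
        if self.task not in BLOCK_STRUCTURE:
            raise ValueError(f"unknown task {self.task!r}")
        for name in ("cue_dur", "cue_to_lever", "press_to_outcome",
                     "trial_period", "beta_dur"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta_dur >= self.trial_period:
            raise ValueError("burst duration must be shorter than the trial period")
        for p in (*self.burst_prob.values(), self.omission_prob,
                  self.win_stay, self.lose_shift, self.invalid_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for u in self.units:
            if u.kappa < 0:
                raise ValueError(f"unit {u.unit_id}: kappa must be >= 0")


@dataclass
class GroundTruth:
    """What the simulator actually injected, for oracle-style tests."""

    burst_intervals: list[tuple[float, float, int]]  # (onset, offset, trial or -1)
    unit_params: list[UnitSpec] = field(default_factory=list)
    choice_policy: dict = field(default_factory=dict)

    def intervals(self) -> np.ndarray:
        if not self.burst_intervals:
            return np.empty((0, 2))
        return np.array([(a, b) for a, b, _ in self.burst_intervals])


def _forced_levers(n_forced: int, rng: np.random.Generator) -> list[str]:
    half = n_forced // 2
    levers = ["small"] * half + ["large"] * (n_forced - half)
    rng.shuffle(levers)
    return levers


def generate_trials(cfg: SimConfig, seed: int | None = None) -> EventLog:
    """Generate the task event log for one session.

    Timing is exact by construction: ``cue_off = cue_on + 2``, levers at
    ``cue_on + 5``, outcome at ``press + 3``, consecutive cue onsets 40 s
    apart. Forced-lever order is pseudorandomized (half per lever, per
    block); free choices follow a win-stay / lose-shift policy.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    p_win = cfg.reward_schedule()
    n_forced, n_free = BLOCK_STRUCTURE[cfg.task]
    rows: list[tuple] = []
    t_cue = cfg.rest_dur
    trial = 0
    prev_lever, prev_outcome = None, None
    for block in range(cfg.n_blocks):
        levers = _forced_levers(n_forced, rng)
        for k in range(n_forced + n_free):
            if k < n_forced:
                trial_type, lever = "forced", levers[k]
            else:
                trial_type = "free"
                if prev_lever is None:
                    lever = rng.choice(["small", "large"])
                elif prev_outcome == "win":
                    stay = rng.random() < cfg.win_stay
                    lever = prev_lever if stay else _other(prev_lever)
                else:
                    shift = rng.random() < cfg.lose_shift
                    lever = _other(prev_lever) if shift else prev_lever

            omitted = rng.random() < cfg.omission_prob
            t_lever = t_cue + cfg.cue_dur + cfg.cue_to_lever
            ev = [(t_cue, "trial_start"), (t_cue, "cue_on"),
                  (t_cue + cfg.cue_dur, "cue_off"), (t_lever, "lever_extend")]
            if omitted:
                lever_out, outcome = "none", "none"
            else:
                t_press = t_lever + rng.uniform(*cfg.press_latency)
                t_release = t_press + rng.uniform(*cfg.hold_dur)
                t_outcome = t_press + cfg.press_to_outcome
                t_poke = t_release + rng.lognormal(np.log(cfg.rt_median),
                                                   cfg.rt_sigma)
                outcome = "win" if rng.random() < p_win.get(lever, 1.0) \
                    else "loss"
                lever_out = lever
                ev += [(t_press, "lever_press"), (t_release, "lever_release"),
                       (t_poke, "nose_poke")]
                if outcome == "win":
                    ev.append((t_outcome, "reward"))
            for t, kind in sorted(ev):
                rows.append((t, kind, trial, block, lever_out, outcome,
                             trial_type))
            if trial_type == "free" and not omitted:
                prev_lever, prev_outcome = lever, outcome
            trial += 1
            t_cue += cfg.trial_period
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EventLog(df.sort_values("time", kind="stable"))


def _other(lever: str) -> str:
    return "large" if lever == "small" else "small"


def session_duration(cfg: SimConfig, events: EventLog) -> float:
    if len(events.table) == 0:
        return cfg.rest_dur + 10.0
    return float(events.table["time"].max() + 15.0)


def one_over_f_noise(n: int, rate: float, exponent: float, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def beta_burst_waveform(duration: float, freq: float, amp: float,
                        rate: float, taper: float = 0.25) -> np.ndarray:
    """Tapered cosine burst; phase 0 (= oscillation peak) at onset.

    The envelope is a Tukey window: Hann-shaped on/offsets over a
    ``taper`` fraction of the burst (smooth edges avoid broadband
    artifacts that would confound detector tests) around a constant
    plateau, so a burst's nominal duration matches the time its power
    is actually sustained. ``taper=1`` degenerates to a full Hann
    envelope.
    """
    from scipy.signal.windows import tukey
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    return amp * tukey(n, alpha=taper) * np.cos(2 * np.pi * freq * t)


def generate_lfp(cfg: SimConfig, events: EventLog,
                 seed: int | None = None) -> tuple[LFPRecording, GroundTruth]:
    """Synthesize the LFP trace and record every injected β interval.

    Bursts are placed at ``nose_poke + latency`` (Gaussian jitter) on
    trials selected with the age-group burst probability, plus a
    Poisson stream of spontaneous bursts if configured; overlapping
    candidates are dropped so ground-truth intervals are disjoint.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    dur = session_duration(cfg, events)
    n = int(round(dur * cfg.lfp_rate))
    x = one_over_f_noise(n, cfg.lfp_rate, cfg.noise_exponent, cfg.noise_sd, rng)
    t = np.arange(n) / cfg.lfp_rate
    mod = 1.0 + cfg.theta_mod_depth * np.sin(
        2 * np.pi * cfg.theta_mod_freq * t + rng.uniform(0, 2 * np.pi))
    x += cfg.theta_amp * mod * np.sin(2 * np.pi * cfg.theta_freq * t)

    p_burst = cfg.burst_prob.get(cfg.age_group, 0.0)
    candidates: list[tuple[float, int]] = []
    df = events.table
    pokes = df[df["kind"] == "nose_poke"]
    for _, row in pokes.iterrows():
        if rng.random() < p_burst:
            onset = row["time"] + rng.normal(cfg.beta_latency_mean,
                                             cfg.beta_latency_sd)
            candidates.append((float(onset), int(row["trial_index"])))
    if cfg.spontaneous_rate > 0:
        n_spont = rng.poisson(cfg.spontaneous_rate * dur)
        for onset in rng.uniform(0, dur - cfg.beta_dur, size=n_spont):
            candidates.append((float(onset), -1))
    candidates.sort()

    wave = beta_burst_waveform(cfg.beta_dur, cfg.beta_freq,
                               cfg.beta_amp_sd * cfg.noise_sd, cfg.lfp_rate,
                               taper=cfg.beta_taper)
    intervals: list[tuple[float, float, int]] = []
    last_end = -np.inf
    for onset, trial in candidates:
        i0 = int(round(onset * cfg.lfp_rate))
        if onset <= last_end or i0 < 0 or i0 + wave.size > n:
            continue
        x[i0:i0 + wave.size] += wave
        onset_s = i0 / cfg.lfp_rate
        offset_s = (i0 + wave.size) / cfg.lfp_rate
        intervals.append((onset_s, offset_s, trial))
        last_end = offset_s
    gt = GroundTruth(burst_intervals=intervals, unit_params=list(cfg.units),
                     choice_policy={"win_stay": cfg.win_stay,
                                    "lose_shift": cfg.lose_shift})
    return LFPRecording(x, rate=cfg.lfp_rate, t0=0.0), gt


def _base_train(pattern: str, rate: float, duration: float,
                rng: np.random.Generator) -> np.ndarray:
    """Baseline spike times on [0, duration) for one firing-pattern class."""
    if rate <= 0 or duration <= 0:
        return np.empty(0)
    n_target = int(rate * duration * 1.5) + 20
    if pattern == "tonic":
        # gamma renewal, shape 10 -> low-CV clock-like train
        shape = 10.0
        isis = rng.gamma(shape, 1.0 / (rate * shape), size=n_target)
    elif pattern == "irregular":
        isis = rng.exponential(1.0 / rate, size=n_target)
    elif pattern == "bursty":
        # bursts of 3-6 spikes at ~5 ms ISI separated by long exponential gaps
        spikes_per_burst = 4.5
        burst_rate = rate / spikes_per_burst
        times = []
        t = rng.exponential(1.0 / burst_rate)
        while t < duration:
            n_b = rng.integers(3, 7)
            intra = np.clip(0.005 * (1 + 0.3 * rng.standard_normal(n_b - 1)),
                            0.002, 0.012)
            burst = t + np.concatenate([[0.0], np.cumsum(intra)])
            times.extend(burst[burst < duration])
            t = burst[-1] + rng.exponential(1.0 / burst_rate)
        return np.unique(np.asarray(times))
    else:
        raise ValueError(f"unknown firing pattern {pattern!r}")
    times = np.cumsum(isis)
    return times[times < duration]


def von_mises_phases(mu_deg: float, kappa: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample spike phases in degrees [0, 360); kappa=0 gives uniform."""
    if kappa == 0:
        return rng.uniform(0.0, 360.0, size=n)
    return np.degrees(rng.vonmises(np.radians(mu_deg), kappa, size=n)) % 360.0


def generate_spikes(cfg: SimConfig, lfp: LFPRecording, gt: GroundTruth,
                    seed: int | None = None) -> list[SpikeTrain]:
    """Generate spike trains; phase-locked units fire at von Mises phases
    of the injected burst waveform inside ground-truth β intervals."""
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    duration = lfp.duration
    trains = []
    for u in cfg.units:
        times = _base_train(u.pattern, u.rate, duration, rng)
        if u.phase_locked and gt.burst_intervals:
            keep = np.ones(times.size, dtype=bool)
            locked = []
            for onset, offset, _ in gt.burst_intervals:
                keep &= ~((times >= onset) & (times < offset))
                n_cycles = int(np.floor((offset - onset) * cfg.beta_freq))
                if n_cycles == 0:
                    continue
                n_sp = rng.poisson(u.burst_rate_hz * (offset - onset))
                if n_sp == 0:
                    continue
                phases = von_mises_phases(u.mu_deg, u.kappa, n_sp, rng)
                cycles = rng.integers(0, n_cycles, size=n_sp)
                locked.append(onset + (cycles + phases / 360.0) / cfg.beta_freq)
            times = np.concatenate([times[keep]] + locked)
        times = np.unique(times)
        times = times[(times >= 0) & (times < duration)]
        times = _enforce_refractory(times, cfg.spike_refractory)
        trains.append(SpikeTrain(u.unit_id, times,
                                 rest_window=(0.0, cfg.rest_dur)))
    return trains


def _enforce_refractory(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedily drop spikes closer than ``refractory`` to the previous one."""
    if times.size == 0 or refractory <= 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory:
            keep.append(t)
    return np.asarray(keep)


def generate_position(cfg: SimConfig, events: EventLog,
                      seed: int | None = None) -> PositionTrack:
    """Simulate goal-directed head tracking at 60 Hz.

    The animal waits near the chamber center, approaches the cued lever
    before the press, runs lever→feeder so as to arrive at the nose
    poke, dwells at the feeder through reward delivery, then returns.
    A configurable fraction of samples is flagged invalid (light
    interference) to exercise interpolation and the 40 % rejection rule.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    dur = session_duration(cfg, events)
    center = (float(np.mean([v[0] for v in cfg.chamber_vertices])),
              float(np.mean([v[1] for v in cfg.chamber_vertices])))
    way_t, way_xy = [0.0], [center]

    df = events.table
    for trial in sorted(df.loc[df["kind"] == "trial_start", "trial_index"].unique()):
        tr = df[df["trial_index"] == trial]

        def t_of(kind):
            v = tr.loc[tr["kind"] == kind, "time"].to_numpy()
            return float(v[0]) if v.size else None

        press, poke = t_of("lever_press"), t_of("nose_poke")
        if press is None:
            continue
        lever = tr["lever"].iloc[0]
        lever_xy = cfg.lever_px.get(lever, center)
        way_t += [press - 2.0, press]
        way_xy += [center, lever_xy]
        if poke is not None:
            dwell_end = poke + 3.0
            way_t += [poke, dwell_end, dwell_end + 3.0]
            way_xy += [cfg.feeder_px, cfg.feeder_px, center]
    way_t.append(dur)
    way_xy.append(center)
    way_t = np.asarray(way_t)
    way_xy = np.asarray(way_xy, dtype=float)
    order = np.argsort(way_t, kind="stable")
    way_t, way_xy = way_t[order], way_xy[order]

    times = np.arange(0.0, dur, 1.0 / cfg.pos_rate)
    x = np.interp(times, way_t, way_xy[:, 0]) \
        + cfg.pos_jitter_px * rng.standard_normal(times.size)
    y = np.interp(times, way_t, way_xy[:, 1]) \
        + cfg.pos_jitter_px * rng.standard_normal(times.size)
    valid = rng.random(times.size) >= cfg.invalid_fraction
    return PositionTrack(times, x, y, valid, cm_per_px=cfg.cm_per_px)


def generate_session(cfg: SimConfig, seed: int | None = None
                     ) -> tuple[SessionBundle, GroundTruth]:
    """Generate a full session bundle plus its ground truth.

    Reproducible: identical ``(cfg, seed)`` gives bit-identical output.
    """
    base = cfg.seed if seed is None else seed
    events = generate_trials(cfg, seed=base)
    lfp, gt = generate_lfp(cfg, events, seed=base + 1)
    spikes = generate_spikes(cfg, lfp, gt, seed=base + 2)
    position = generate_position(cfg, events, seed=base + 3)
    meta = {"subject_id": cfg.subject_id, "age_group": cfg.age_group,
            "task": cfg.task, "day": cfg.day, "phase": cfg.phase,
            "cm_per_px": cfg.cm_per_px,
            "rest_window": [0.0, cfg.rest_dur]}
    bundle = SessionBundle(lfp=lfp, spikes=spikes, events=events,
                           position=position, meta=meta)
    return bundle, gt


def write_ground_truth(path, gt: GroundTruth) -> None:
    """Write ground-truth burst intervals and unit parameters as TSV."""
    import pathlib
    path = pathlib.Path(path)
    pd.DataFrame(gt.burst_intervals,
                 columns=["onset_s", "offset_s", "trial_index"]).to_csv(
        path / "ground_truth.tsv", sep="\t", index=False)
    pd.DataFrame([vars(u) for u in gt.unit_params]).to_csv(
        path / "ground_truth_units.tsv", sep="\t", index=False)
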