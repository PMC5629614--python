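"""Session data model and on-disk I/O.

A recording session bundles one LFP channel (optionally a reference
channel), sorted spike trains, a task event log, and a video position
track, all on a single session clock (seconds from session start,
half-open windows ``[a, b)`` throughout the package).

On disk a session is a directory of plain-text files plus one raw
float32 trace per LFP channel:

* ``lfp.bin`` / ``lfp.json`` — little-endian float32 samples and a
  sidecar with ``rate`` (samples/s), ``t0`` (s) and ``units``;
* ``reference_lfp.bin`` / ``reference_lfp.json`` — optional;
* ``spikes.tsv`` — ``unit_id``, ``time_s``;
* ``events.tsv`` — one task event per row;
* ``position.tsv`` — 60 Hz head tracking with validity flags;
* ``session.yaml`` — subject/task metadata, pixel scale, rest window.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EVENT_KINDS = frozenset(
    {"cue_on", "cue_off", "lever_extend", "lever_press", "lever_release",
     "nose_poke", "reward", "trial_start"}
)
LEVERS = frozenset({"small", "large", "none"})
OUTCOMES = frozenset({"win", "loss", "none"})
TRIAL_TYPES = frozenset({"forced", "free"})

EVENT_COLUMNS = ["time", "kind", "trial_index", "block_index", "lever",
                 "outcome", "trial_type"]


class SessionFormatError(ValueError):
    """A session file is missing or violates a data-model invariant."""


@dataclass
class LFPRecording:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in µV (nominal; absolute gain is not modeled, all
        detection thresholds downstream are scale-relative).
    rate : float
        Sampling rate in samples/s. The acquisition default is 1871 Hz.
    t0 : float
        Session time of the first sample, in seconds.
    """

    samples: np.ndarray
    rate: float = 1871.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise SessionFormatError(f"LFP rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the trace in seconds."""
        return self.n / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def index_of(self, t: float | np.ndarray):
        """Nearest sample index for session time ``t`` (clipped to range)."""
        idx = np.rint((np.asarray(t) - self.t0) * self.rate).astype(int)
        return np.clip(idx, 0, self.n - 1)


@dataclass
class SpikeTrain:
    """Sorted spike timestamps for one unit, with its pre-task rest window."""

    unit_id: str
    times: np.ndarray
    rest_window: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise SessionFormatError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )

    @property
    def n(self) -> int:
        return self.times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class EventLog:
    """Timestamped task events (cue, lever, nose-poke, reward) per trial."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True)
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise SessionFormatError(f"event log missing columns {sorted(missing)}")
        self.table = df[EVENT_COLUMNS]
        self.validate()

    def validate(self) -> None:
        df = self.table
        if len(df) == 0:
            return
        bad_kind = set(df["kind"]) - EVENT_KINDS
        if bad_kind:
            raise SessionFormatError(f"unknown event kinds {sorted(bad_kind)}")
        if not df["time"].is_monotonic_increasing:
            raise SessionFormatError("event times must be nondecreasing")
        starts = df[df["kind"] == "trial_start"]["trial_index"]
        if starts.duplicated().any():
            dup = int(starts[starts.duplicated()].iloc[0])
            raise SessionFormatError(f"trial {dup} has more than one trial_start")
        by_trial = df.pivot_table(index="trial_index", columns="kind",
                                  values="time", aggfunc="first")
        if {"lever_press", "lever_release"} <= set(by_trial.columns):
            both = by_trial.dropna(subset=["lever_press", "lever_release"])
            bad = both[both["lever_release"] < both["lever_press"]]
            if len(bad):
                raise SessionFormatError(
                    f"trial {int(bad.index[0])}: lever_release precedes lever_press"
                )

    def times_of(self, kind: str) -> np.ndarray:
        return self.table.loc[self.table["kind"] == kind, "time"].to_numpy(float)

    @property
    def n_trials(self) -> int:
        return int((self.table["kind"] == "trial_start").sum())


@dataclass
class PositionTrack:
    """60 Hz head position in camera pixels with per-sample validity."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    cm_per_px: float = 0.2

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.times.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise SessionFormatError("position arrays must share one length")
        if n > 1 and np.any(np.diff(self.times) < 0):
            raise SessionFormatError("position times must be nondecreasing")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - self.valid.mean()) if self.n else 0.0


@dataclass
class SessionBundle:
    """All streams of one recording session on a shared clock."""

    lfp: LFPRecording
    spikes: list[SpikeTrain]
    events: EventLog
    position: PositionTrack
    reference_lfp: LFPRecording | None = None
    meta: dict = field(default_factory=dict)


def _read_lfp(stem: Path) -> LFPRecording:
    bin_path = stem.with_suffix(".bin")
    sidecar = stem.with_suffix(".json")
    for p in (bin_path, sidecar):
        if not p.exists():
            raise SessionFormatError(f"missing session file: {p.name}")
    meta = json.loads(sidecar.read_text())
    samples = np.fromfile(bin_path, dtype="<f4").astype(float)
    return LFPRecording(samples, rate=float(meta["rate"]), t0=float(meta.get("t0", 0.0)))


def _write_lfp(stem: Path, lfp: LFPRecording) -> None:
    lfp.samples.astype("<f4").tofile(stem.with_suffix(".bin"))
    stem.with_suffix(".json").write_text(
        json.dumps({"rate": lfp.rate, "t0": lfp.t0, "units": "uV"}))


def read_session(path: str | Path) -> SessionBundle:
    """Read a session directory into a validated :class:`SessionBundle`."""
    path = Path(path)
    for name in ("lfp.bin", "lfp.json", "spikes.tsv", "events.tsv",
                 "position.tsv", "session.yaml"):
        if not (path / name).exists():
            raise SessionFormatError(f"missing session file: {name}")
    meta = yaml.safe_load((path / "session.yaml").read_text()) or {}
    lfp = _read_lfp(path / "lfp")
    reference = _read_lfp(path / "reference_lfp") \
        if (path / "reference_lfp.bin").exists() else None

    rest = tuple(meta.get("rest_window", (0.0, 0.0)))
    spk = pd.read_csv(path / "spikes.tsv", sep="\t")
    spikes = [SpikeTrain(str(uid), g["time_s"].to_numpy(float), rest_window=rest)
              for uid, g in spk.groupby("unit_id", sort=True)]

    ev = pd.read_csv(path / "events.tsv", sep="\t",
                     dtype={"kind": str, "lever": str, "outcome": str,
                            "trial_type": str},
                     keep_default_na=False)
    ev["trial_index"] = ev["trial_index"].astype(int)
    ev["block_index"] = ev["block_index"].astype(int)
    events = EventLog(ev)

    pos = pd.read_csv(path / "position.tsv", sep="\t")
    position = PositionTrack(pos["time_s"].to_numpy(), pos["x_px"].to_numpy(),
                             pos["y_px"].to_numpy(),
                             pos["valid"].to_numpy(bool),
                             cm_per_px=float(meta.get("cm_per_px", 0.2)))
    return SessionBundle(lfp=lfp, spikes=spikes, events=events,
                         position=position, reference_lfp=reference, meta=meta)


def write_session(path: str | Path, bundle: SessionBundle) -> Path:
    """Write a :class:`SessionBundle` to a session directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_lfp(path / "lfp", bundle.lfp)
    if bundle.reference_lfp is not None:
        _write_lfp(path / "reference_lfp", bundle.reference_lfp)
    rows = [(tr.unit_id, t) for tr in bundle.spikes for t in tr.times]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False)
    bundle.events.table.to_csv(path / "events.tsv", sep="\t", index=False)
    pos = bundle.position
    pd.DataFrame({"time_s": pos.times, "x_px": pos.x, "y_px": pos.y,
                  "valid": pos.valid.astype(int)}).to_csv(
        path / "position.tsv", sep="\t", index=False)
    meta = dict(bundle.meta)
    meta.setdefault("cm_per_px", pos.cm_per_px)
    if bundle.spikes:
        meta.setdefault("rest_window", list(bundle.spikes[0].rest_window))
    (path / "session.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def build_trial_table(events: EventLog) -> pd.DataFrame:
    """Roll the event log up into one row per trial.

    Columns: ``trial_index, block_index, trial_type, lever, outcome,
    cue_on_t, press_t, release_t, nosepoke_t, reward_t, reaction_time``.
    ``reaction_time`` is lever release to nose poke, seconds; missing
    events (e.g. a failure to press within the 20 s response window)
    leave NaN in the corresponding columns. A second press inside one
    trial keeps the first and logs a warning.
    """
    df = events.table
    rows = []
    for idx in sorted(df.loc[df["kind"] == "trial_start", "trial_index"].unique()):
        tr = df[df["trial_index"] == idx]
        first = {}
        for kind in ("cue_on", "lever_press", "lever_release", "nose_poke", "reward"):
            t = tr.loc[tr["kind"] == kind, "time"].to_numpy()
            if kind == "lever_press" and t.size > 1:
                logger.warning("trial %d: %d lever presses, keeping the first",
                               idx, t.size)
            first[kind] = float(t[0]) if t.size else np.nan
        lever = tr["lever"].iloc[0]
        outcome = tr["outcome"].iloc[0]
        trial_type = tr["trial_type"].iloc[0]
        block = int(tr["block_index"].iloc[0])
        rt = first["nose_poke"] - first["lever_release"]
        rows.append({
            "trial_index": int(idx), "block_index": block,
            "trial_type": trial_type, "lever": lever, "outcome": outcome,
            "cue_on_t": first["cue_on"], "press_t": first["lever_press"],
            "release_t": first["lever_release"],
            "nosepoke_t": first["nose_poke"], "reward_t": first["reward"],
            "reaction_time": rt,
        })
    table = pd.DataFrame(rows, columns=[
        "trial_index", "block_index", "trial_type", "lever", "outcome",
        "cue_on_t", "press_t", "release_t", "nosepoke_t", "reward_t",
        "reaction_time"])
    neg = table["reaction_time"] < 0
    if neg.any():
        warnings.warn(f"{int(neg.sum())} trials with negative reaction time")
    return table
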