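"""End-to-end session analysis: chains preprocessing, β-event
detection, unit statistics and spatial mapping, and writes the
tabular outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import lfp as lp
from . import spatial as sp
from . import units as un
from .session import SessionBundle, build_trial_table

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Analysis parameters (defaults are the published values)."""

    detection_band: tuple[float, float] = ev.DETECTION_BAND
    spectral_band: tuple[float, float] = ev.SPECTRAL_BAND
    k_sd: float = 2.0
    min_dur: float = 0.350
    smooth: float = 0.100
    task_window: float = 3.0
    post_window: tuple[float, float] = (0.1, 2.9)
    baseline_window: tuple[float, float] = (-2.9, -0.1)
    n_sub: int = 50
    max_invalid: float = 0.40
    pos_smooth: float = 0.5
    velocity_window: float = 0.5
    reward_zone_px: tuple[float, float, float, float] = (215.0, 445.0, 50.0, 100.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown analysis key {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        return cfg


@dataclass
class SessionResult:
    trials: pd.DataFrame
    beta_events: list
    incidence: ev.IncidenceRecord
    band_power: list
    unit_table: pd.DataFrame
    phase_table: pd.DataFrame
    heatmap: sp.BetaPowerMap | None
    occupancy: sp.OccupancyMap | None
    onsets: list
    velocity: tuple[np.ndarray, np.ndarray]
    spatial_rejected: str | None = None


def analyze_session(bundle: SessionBundle,
                    cfg: AnalysisConfig | None = None) -> SessionResult:
    """Run the full analysis chain on one session."""
    cfg = cfg or AnalysisConfig()
    trials = build_trial_table(bundle.events)

    all_spikes = np.sort(np.concatenate(
        [s.times for s in bundle.spikes])) if bundle.spikes else np.empty(0)
    despiked = lp.despike(bundle.lfp, all_spikes)
    beta_filtered = lp.bandpass(despiked, *cfg.detection_band)

    detected = ev.detect_beta_events(despiked, band=cfg.detection_band,
                                     k_sd=cfg.k_sd, min_dur=cfg.min_dur,
                                     smooth=cfg.smooth)
    ev.classify_task_evoked(detected, trials, window=cfg.task_window)
    incidence = ev.beta_incidence(detected, trials, bundle.meta)
    band_power = lp.trial_band_power(despiked, trials, cfg.spectral_band,
                                     post_window=cfg.post_window,
                                     baseline_window=cfg.baseline_window)

    unit_rows, phase_rows = [], []
    for k, train in enumerate(bundle.spikes):
        cl = un.classify_train(train)
        unit_rows.append({"unit_id": cl.unit_id, "included": cl.included,
                          "lv": cl.lv, "ac_decay": cl.ac_decay,
                          "isi_bimodal": cl.isi_bimodal,
                          "category": cl.category})
        if not cl.included:
            continue
        sample = un.spike_beta_phases(train, beta_filtered, detected,
                                      n_sub=cfg.n_sub, seed=cfg.seed + k)
        if sample is None:
            continue
        res = un.rayleigh_test(sample.phases)
        phase_rows.append({"unit_id": sample.unit_id, "n": res.n,
                           "r": res.r, "z": res.z, "p": res.p,
                           "mean_angle_deg": res.mean_angle})
    unit_table = pd.DataFrame(unit_rows)
    phase_table = pd.DataFrame(
        phase_rows, columns=["unit_id", "n", "r", "z", "p", "mean_angle_deg"])

    heatmap = occupancy = None
    onsets: list = []
    velocity = (np.empty(0), np.empty(0))
    spatial_rejected = None
    try:
        track = sp.clean_track(bundle.position, max_invalid=cfg.max_invalid,
                               smooth=cfg.pos_smooth)
        occupancy = sp.occupancy_map(track)
        env = ev.smoothed_squared_power(despiked, band=cfg.detection_band,
                                        smooth=cfg.smooth)
        power60 = sp.subsample_power(env, despiked.times(), track.times)
        heatmap = sp.beta_power_heatmap(track, power60)
        onsets = sp.beta_onset_locations(detected, track)
        task_onsets = [e.onset for e in detected if e.task_evoked]
        velocity = sp.movement_velocity(track, task_onsets,
                                        window=cfg.velocity_window,
                                        baseline_ref=trials["cue_on_t"].dropna())
    except sp.SessionRejected as exc:
        spatial_rejected = str(exc)
        logger.warning("spatial analyses skipped: %s", exc)

    return SessionResult(trials=trials, beta_events=detected,
                         incidence=incidence, band_power=band_power,
                         unit_table=unit_table, phase_table=phase_table,
                         heatmap=heatmap, occupancy=occupancy, onsets=onsets,
                         velocity=velocity, spatial_rejected=spatial_rejected)


def write_outputs(result: SessionResult, out_dir) -> Path:
    """Write the session result as the TSV/JSON output set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"onset": e.onset, "offset": e.offset,
                   "duration": e.duration,
                   "peak_squared_power": e.peak_squared_power,
                   "trial_index": e.trial_index if e.trial_index is not None
                   else -1,
                   "task_evoked": int(e.task_evoked)}
                  for e in result.beta_events]).to_csv(
        out / "beta_events.tsv", sep="\t", index=False)
    inc = result.incidence
    pd.DataFrame([{"session_id": inc.session_id, "day": inc.day,
                   "task": inc.task, "age_group": inc.age_group,
                   "n_task_evoked_events": inc.n_task_evoked_events,
                   "n_trials": inc.n_trials,
                   "incidence": inc.incidence}]).to_csv(
        out / "incidence.tsv", sep="\t", index=False)
    pd.DataFrame([{"trial_index": r.trial_index, "band_lo": r.band[0],
                   "band_hi": r.band[1], "post": r.post_power,
                   "baseline": r.baseline_power, "difference": r.difference}
                  for r in result.band_power]).to_csv(
        out / "band_power.tsv", sep="\t", index=False)
    result.unit_table.to_csv(out / "units.tsv", sep="\t", index=False)
    result.phase_table.to_csv(out / "phases.tsv", sep="\t", index=False)
    result.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
    if result.heatmap is not None:
        np.savetxt(out / "heatmap.tsv", result.heatmap.grid, delimiter="\t")
        pd.DataFrame(result.onsets,
                     columns=["x_px", "y_px", "task_evoked"]).to_csv(
            out / "onsets.tsv", sep="\t", index=False)
        speeds, base = result.velocity
        pd.DataFrame({"kind": ["event"] * speeds.size + ["baseline"] * base.size,
                      "speed_cm_s": np.concatenate([speeds, base])}).to_csv(
            out / "velocity.tsv", sep="\t", index=False)
    summary = {"n_trials": int(inc.n_trials),
               "n_beta_events": len(result.beta_events),
               "incidence": inc.incidence,
               "spatial_rejected": result.spatial_rejected}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out
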