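import numpy as np
import pytest

import betamyg as bm


@pytest.fixture(scope="session")
def high_burst_session():
    """Two-block old-rat session with near-certain per-trial bursts and
    strongly phase-locked units; shared by detection/phase/spatial tests."""
    cfg = bm.SimConfig(n_blocks=2, burst_prob={"old": 0.9, "young": 0.05})
    bundle, gt = bm.generate_session(cfg, seed=11)
    return cfg, bundle, gt


@pytest.fixture(scope="session")
def analyzed(high_burst_session):
    _, bundle, _ = high_burst_session
    return bm.analyze_session(bundle)


def make_noise_lfp(seed, duration=120.0, rate=1871.0, sd=50.0, exponent=1.0):
    from betamyg.simulate import one_over_f_noise
    rng = np.random.default_rng(seed)
    x = one_over_f_noise(int(rate * duration), rate, exponent, sd, rng)
    return bm.LFPRecording(x, rate=rate)


def inject_bursts(lfp, onsets, duration=0.5, freq=22.0, amp=200.0, taper=0.25):
    """Add tapered bursts at given onsets; returns (lfp, intervals)."""
    from betamyg.simulate import beta_burst_waveform
    wave = beta_burst_waveform(duration, freq, amp, lfp.rate, taper=taper)
    x = lfp.samples.copy()
    intervals = []
    for o in onsets:
        i0 = int(round(o * lfp.rate))
        x[i0:i0 + wave.size] += wave
        intervals.append((i0 / lfp.rate, (i0 + wave.size) / lfp.rate))
    return bm.LFPRecording(x, rate=lfp.rate, t0=lfp.t0), intervals


def match_events(events, intervals):
    """Greedy matching: overlap >= 50% of the shorter interval."""
    matched = set()
    tp = 0
    for e in events:
        for k, (a, b) in enumerate(intervals):
            if k in matched:
                continue
            ov = max(0.0, min(e.offset, b) - max(e.onset, a))
            if ov >= 0.5 * min(e.duration, b - a):
                matched.add(k)
                tp += 1
                break
    return tp
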