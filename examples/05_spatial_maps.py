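"""Where do β events happen in the chamber?

The position track is cleaned (spline interpolation of invalid
samples, 500 ms Hamming smoothing; sessions over 40% invalid are
rejected), then used for reward-zone occupancy, an occupancy-
normalized 24 x 30 β-power map, the head position at each β onset,
and movement speed over the 0.5 s after each onset vs a pre-cue
baseline.
"""

import numpy as np
from scipy import stats as sps

import betamyg as bm
from betamyg.spatial import in_rectangle

cfg = bm.SimConfig(n_blocks=3, age_group="old",
                   burst_prob={"old": 0.9, "young": 0.05})
bundle, truth = bm.generate_session(cfg, seed=4)
result = bm.analyze_session(bundle)
trials = result.trials

track = bm.clean_track(bundle.position)
occ = bm.reward_zone_occupancy(track, cfg.reward_zone_px, trials)
print(f"reward-zone occupancy during pressed trials: {occ:.2f}")

onsets = [(x, y) for x, y, evoked in result.onsets if evoked]
if onsets:
    xs, ys = np.array(onsets).T
    frac = in_rectangle(xs, ys, cfg.reward_zone_px).mean()
    print(f"task-evoked β onsets inside the reward zone: {frac:.2f} "
          f"({len(onsets)} events)")

speeds, base = result.velocity
if speeds.size and base.size:
    p = sps.mannwhitneyu(speeds, base, alternative="greater").pvalue
    print(f"speed at β onset {speeds.mean():.1f} cm/s vs pre-cue baseline "
          f"{base.mean():.1f} cm/s (rank test p = {p:.3g})")
print("\nBursts are injected at the nose poke, so their onset locations")
print("cluster at the food cup and the animal is still decelerating --")
print("event-onset speeds exceed the waiting-period baseline.")
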