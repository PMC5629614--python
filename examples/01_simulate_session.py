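"""Generate a synthetic recording session and inspect its structure.

A reward-magnitude session runs 5 blocks of 8 forced + 6 free-choice
trials (70 trials, one cue onset every 40 s). The simulator injects β
bursts just after the nose poke on a per-trial coin flip and records
every injected interval as ground truth.
"""

import betamyg as bm

cfg = bm.SimConfig(task="reward_magnitude", age_group="old", seed=0)
bundle, truth = bm.generate_session(cfg, seed=0)

trials = bm.build_trial_table(bundle.events)
print(f"trials: {len(trials)} in {trials['block_index'].nunique()} blocks")
print(f"LFP: {bundle.lfp.n} samples at {bundle.lfp.rate} Hz "
      f"({bundle.lfp.duration / 60:.1f} min)")
print(f"units: {[s.unit_id for s in bundle.spikes]}")
print(f"injected β bursts: {len(truth.burst_intervals)} "
      f"(per-trial probability {cfg.burst_prob['old']})")
print(f"median reaction time: {trials['reaction_time'].median():.2f} s "
      "(lever release to nose poke)")

# The trial cycle is exact: outcome 3 s after the press, 40 s period.
import numpy as np
by = bundle.events.table.pivot_table(index="trial_index", columns="kind",
                                     values="time", aggfunc="first")
won = by.dropna(subset=["reward"])
print(f"outcome delay: {np.unique(won['reward'] - won['lever_press'])[0]} s; "
      f"cue period: {np.unique(np.diff(np.sort(by['cue_on'])))[0]} s")
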