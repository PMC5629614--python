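"""Spike-β phase locking through the full analysis chain.

A session is generated with two phase-locked units (von Mises
concentration kappa=4 around mu=18 deg, 0 deg = oscillation peak) and
three unlocked units. The pipeline de-spikes the LFP, detects β
events, extracts spike phases from the Hilbert-transformed 20-40 Hz
signal inside the detected epochs, subsamples 50 spikes per unit, and
runs the Rayleigh test with its exponential p-approximation.
"""

import betamyg as bm

cfg = bm.SimConfig(n_blocks=3, age_group="old",
                   burst_prob={"old": 0.9, "young": 0.05})
bundle, truth = bm.generate_session(cfg, seed=2)
result = bm.analyze_session(bundle)

print(f"β events detected: {len(result.beta_events)} "
      f"({result.incidence.n_task_evoked_events} task-evoked)")
print()
print("unit   n    r      z       p         mean phase")
for _, row in result.phase_table.iterrows():
    locked = row["p"] < 0.05
    print(f"{row['unit_id']}  {row['n']:3d}  {row['r']:.3f}  "
          f"{row['z']:6.2f}  {row['p']:.2e}  {row['mean_angle_deg']:6.1f}°"
          f"  {'<- entrained' if locked else ''}")
print()
print("Units u01 and u03 were injected with kappa=4, mu=18°; their large")
print("resultant length r and tiny Rayleigh p recover that entrainment,")
print("while the unlocked units stay consistent with uniform phases.")
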