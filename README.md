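# betamyg

Analysis of transient β-band (15–40 Hz) oscillations in amygdala local
field potentials recorded during operant decision-making tasks, with a
ground-truth session simulator for validating every stage.

Aged rats develop strong, discrete bursts of β-band activity in the
basolateral amygdala as they reach the reward location after a lever
press, and a substantial fraction of single units fire phase-locked to
those bursts. Studying this phenomenon requires a chain of signal- and
spike-analysis steps — LFP de-spiking, zero-phase band filtering,
envelope thresholding, circular statistics, longitudinal mixed-effects
modeling, spatial mapping — each with parameters whose behavior is hard
to verify on real data, where the ground truth is unknown. `betamyg`
implements the full chain as a tested library and pairs it with a
simulator that generates complete sessions (task event log, LFP with
injected bursts, spike trains with controlled phase locking, position
tracking) in which every quantity the pipeline estimates is known by
construction.

## The core definitions

* **β event**: the de-spiked LFP is bandpass filtered (20–40 Hz,
  fourth-order Butterworth applied forward–backward for zero phase),
  squared, and smoothed with a 100 ms moving average; a maximal run
  above mean + 2 SD (session-wide) lasting ≥ 350 ms is an event.
  The threshold is SD-relative, so detection is invariant to gain.
* **Task-evoked event / incidence**: an event whose onset falls within
  3 s after a lever press; incidence = task-evoked events / trials.
* **Spike–β phase locking**: spikes inside β epochs get the phase of
  the Hilbert-transformed band signal (0° = oscillation peak); 50
  spikes are subsampled per unit and tested with the Rayleigh statistic
  `z = n·r²` with tail probability
  `p ≈ exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))`, `R = n·r`.
* **Firing patterns**: tonic if the local variation of interspike
  intervals LV < 0.5; else bursty if the log-ISI distribution is
  bimodal; else irregular if the autocorrelogram slope < −0.005/ms,
  else irregular/bursty.
* **Incidence model**:
  `Y_it = α + β₁Age_i + β₂Day_t + β₃(Age_i×Day_t) + a_i + b_iDay_t + ε_it`,
  fitted by maximum likelihood with nested likelihood-ratio χ² tests.

## Worked example

```sh
python examples/03_spike_phase_locking.py
```

```
β events detected: 37 (37 task-evoked)

unit   n    r      z       p         mean phase
u00   50  0.103    0.53  5.91e-01   174.6°
u01   50  0.763   29.10  7.62e-16    19.3°  <- entrained
u02   50  0.210    2.21  1.09e-01   356.2°
u03   50  0.782   30.58  7.85e-17    21.4°  <- entrained
u04   50  0.128    0.81  4.45e-01    85.1°
```

The session was simulated with units u01 and u03 phase-locked to the
injected bursts (von Mises κ = 4 around μ = 18°). Running the entire
chain — de-spiking, detection, Hilbert phases, 50-spike subsampling,
Rayleigh test — recovers exactly those two units with mean phases
within a few degrees of the injected preference, while the three
unlocked units stay consistent with uniform phases. The other examples
(`examples/01…05`) walk through session simulation, detector
precision/recall against ground truth, the incidence mixed model, and
the spatial analyses.

A thin CLI wraps the same library code for batch work:

```sh
betamyg simulate --seed 1 --out session/        # session dir + ground truth
betamyg run --session session/ --out results/   # beta_events.tsv, units.tsv, ...
betamyg report --out results/                   # summary figures
```

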