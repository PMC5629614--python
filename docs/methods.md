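# Methods

This note documents the models, conventions, and numerical choices
behind `betamyg`, in the spirit of a package methods appendix. All
times are seconds from session start; every event window is half-open
`[a, b)`.

## Session model and formats

A session bundles one LFP channel (nominal 1871 Hz, µV), an optional
reference channel, per-unit spike trains with a pre-task rest window,
a task event log, and a 60 Hz position track (0.2 cm/px). Streams are
assumed pre-synchronized on one clock; clock skew between acquisition
streams is not modeled. On disk: raw little-endian float32 for LFP
with a JSON sidecar, TSV for everything tabular, YAML for metadata.
Storage of the LFP at float32 limits round-trip fidelity to ~7
significant digits, far below any analysis tolerance.

## Task simulator

The trial cycle is deterministic where the task program is
deterministic: cue on 2 s, levers extended 3 s after cue offset,
outcome exactly 3 s after the lever press, next cue exactly 40 s after
the previous one. Reward-magnitude and lever-training sessions run 5
blocks of 8 forced + 6 free-choice trials (70 trials); the probability
tasks run blocks of 16 + 10 (130 trials). Forced-lever order is a
per-block shuffle with half the trials per lever. Free choices follow
a win-stay/lose-shift policy (defaults 0.8 / 0.6); the probability
tasks make the large lever risky (P(win) = 0.5) while the
magnitude/training tasks reward every press.

Stochastic latencies: press latency uniform 0.8–5 s after lever
extension, hold duration 0.2–0.5 s, and reaction time (lever release →
nose poke at the food cup) lognormal with median 0.8 s. The animal
therefore reaches the food cup well before the outcome lands and waits
there — which is what makes β bursts locked to the nose poke fall
inside the 3 s post-press window that defines task-evoked events. The
pre-task rest phase is 60 s by default: long enough to exercise the
rest-rate inclusion gate at desk scale (real protocols use ≥ 30 min,
which would only make that gate easier to evaluate).

## LFP simulator

Background = white Gaussian noise spectrally shaped to 1/f^a (a = 1 by
default, SD 50 µV) plus a theta sinusoid (7.5 Hz, 25 µV) under slow
sinusoidal amplitude modulation. β bursts are tapered cosines at 22 Hz
(within the 19–26 Hz peak range typical of these recordings), 0.5 s
long, amplitude expressed in multiples of the background SD (default
4×) so that detector experiments are gain-free.

The burst envelope is a Tukey window: Hann-shaped rise and fall over
25 % of the burst around a constant plateau. The smooth edges avoid
the broadband clicks a rectangular gate would inject; the plateau
makes a burst's *nominal* duration equal the time its band power is
actually sustained. A full-Hann envelope does not have this property —
it spends roughly half its nominal duration below any mid-level
threshold, so a "0.5 s" full-Hann burst yields only ~0.3 s of
supra-threshold envelope under the 2 SD rule and would be rejected by
the 350 ms criterion no matter how large its amplitude (both the
threshold and the burst power scale with amplitude squared, so the
supra-threshold fraction saturates). `beta_taper = 1.0` restores the
full-Hann shape for anyone who wants it.

Bursts are placed at nose poke + latency (Gaussian, 0.1 ± 0.15 s) on
trials selected with an age-dependent probability (defaults 0.22 old,
0.05 young — the minimal structure reproducing the reported age
contrast in incidence, read as events per trial), plus an optional
Poisson stream of spontaneous bursts; overlapping candidates are
dropped so ground-truth intervals are disjoint.

## Spike simulator

Baseline trains per class: gamma renewal with shape 10 (tonic,
clock-like, LV ≈ 0.15), Poisson (irregular, LV ≈ 1), and 3–6 spike
bursts at ~5 ms ISIs separated by exponential gaps (bursty, bimodal
log-ISI by construction). Phase-locked units replace their baseline
spikes inside ground-truth bursts with spikes placed at von Mises
phases (μ, κ configurable; 0° = peak of the injected cosine) at an
elevated in-burst rate. Every train is thinned to a 2.5 ms absolute
refractory period: well-isolated units essentially never violate the
2 ms refractory gate, whereas a raw 5 Hz Poisson process would fail
the < 0.3 % criterion about 1 % of the time per ISI.

## Position simulator

Waypoint interpolation: waiting near the chamber center, approach to
the cued lever before the press, a lever→feeder run arriving at the
nose poke, dwell at the feeder through reward delivery, return. Pixel
jitter (SD 1.5 px) and a configurable invalid-sample fraction
(default 5 %) are added on top. The camera frame is 480 × 600 px; the
reward zone is the 10 × 20 cm (50 × 100 px) rectangle in front of the
feeder.

## Preprocessing conventions

* **De-spiking** excises `[t − 1 ms, t + 1 ms)` around each spike
  (overlapping windows merged) and refills with a cubic spline
  anchored on 8 intact samples per side; edge windows fall back to
  nearest-neighbor fill with a warning. Samples outside excision
  windows are returned bit-identical.
* **Band filtering** designs a half-order Butterworth and applies it
  forward and backward (`sosfiltfilt`, default odd-extension padding
  of three filter lengths), so the stated order (default 4) is the
  order of the magnitude response and the phase response is zero.
* **Spectra** are Hann-tapered periodograms in density scaling;
  band power integrates the density over the band. This choice makes
  band power independent of the taper's noise bandwidth: an
  amplitude-A sinusoid contributes A²/2 to its band under any window,
  and with a boxcar the total equals the time-domain mean square to
  machine precision (the Parseval check in the tests). Trial windows
  default to 0.1–2.9 s after lever release vs 2.9–0.1 s before cue
  onset; "power difference" is the raw (not log) difference.
* **Event-aligned spectrograms** are short-time spectra (512-sample
  Hann segments, 75 % overlap) averaged across alignment windows and
  z-scored per frequency against the session-wide distribution.
* **Cross-channel normalization** subtracts the across-tetrode mean
  per session; the output sums to zero exactly.

## β-event detection

Squared 20–40 Hz signal (the identification band; the 15–30 Hz
spectral-analysis band is a named preset), smoothed with a 100 ms
moving average — some envelope smoothing is logically required, since
an unsmoothed squared oscillation crosses zero twice per cycle and
could never stay supra-threshold 350 ms. Threshold = mean + 2 SD of
that envelope over the whole recording (a rest-period baseline is
available in config). Sub-threshold dips ≤ 25 ms are bridged before
run extraction so single noisy samples cannot split an event; runs of
length ≥ 350 ms (inclusive at the boundary, measured as run samples /
rate) become events. Manual artifact rejection is replaced by an
automated rule: a candidate containing ≥ 5 consecutive samples at
≥ 99.5 % of the session's absolute maximum is logged and dropped as
amplifier clipping. Because every ingredient (mean, SD, relative clip
level) is scale-relative, the detected event set is exactly invariant
to any positive gain.

## Circular statistics

Phase convention: 0° at the oscillation peak, increasing with time
(trough = 180°), taken from the angle of the analytic (Hilbert)
signal of the band-filtered LFP. Units with ≥ 50 in-epoch spikes are
subsampled to exactly 50 without replacement (seeded, done once). The
Rayleigh statistic is z = n·r²; its tail probability uses the
exponential approximation
`p ≈ exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))` with R = n·r, clamped to
(0, 1] because the approximation can exceed 1 at tiny r. The tests
verify the approximation empirically: type-I error at n = 50 under
uniform phases falls in [0.04, 0.06] over 20,000 draws, and the mean
direction is recovered with < 2° bias at κ = 2.

## Unit classification

LV is the local variation statistic
`3/(n−1) · Σ ((Iᵢ − Iᵢ₊₁)/(Iᵢ + Iᵢ₊₁))²` — 0 for clock-like trains,
1 for Poisson, 0.75 exactly for alternating ISIs a, 3a. The
autocorrelogram is single-sided over (0, 500] ms at 1 ms bins,
normalized to unit mean so a Poisson train sits flat at 1, and the
decay rate is the slope of a least-squares line over the full span —
a linear fit is what makes the −0.005/ms threshold meaningful.
Bimodality of the smoothed log₁₀-ISI histogram (60 bins, Gaussian
smoothing σ = 2 bins) requires a secondary peak ≥ 10 % of the primary
with the intervening valley < 50 % of the secondary; the rule's
parameters are exposed because no canonical operationalization
exists. Classification precedence: tonic (LV < 0.5) → bursty
(bimodal) → irregular (slope strictly < −0.005/ms) → irregular/bursty;
undefined inputs that are needed to decide yield "unclassified".
Inclusion requires < 0.3 % ISIs under 2 ms and ≥ 0.01 Hz firing in the
rest window.

## Rate modulation

Per-trial spike counts regressed on a β-presence flag (plus optional
covariates) by iteratively reweighted least squares with a Tukey
bisquare loss; designs with fewer than 10 trials in either class or
zero-variance counts are skipped. Under a no-effect simulation the
significant fraction at α = 0.05 sits near chance (~5 %), matching
the interpretation of the observed ~6.5 % as chance-level.

## Incidence mixed model

`incidence ~ age * day` with a per-subject random intercept and random
day slope, Gaussian errors, fitted by maximum likelihood (statsmodels
MixedLM, L-BFGS with a CG/Powell fallback cascade, 300 iterations).
Age is coded 0/1 (young/old); day is the session index from 1;
incidence is modeled at session-day granularity. A singular
random-effects covariance triggers a logged refit with intercept-only
random effects — except inside likelihood-ratio sequences, where both
fits keep one structure so the models stay nested. Confidence
intervals use t quantiles on n_subjects − 2 degrees of freedom rather
than normal quantiles: with a dozen subjects, ML Wald-z intervals for
between-subject contrasts (age, age × day) undercover (~0.91 measured
at the default design), and the t-df correction restores near-nominal
coverage (~0.94) — the same reasoning behind Satterthwaite-style
corrections in longitudinal models. LR tests remain ML χ² with df =
parameter difference; at 13 subjects they are mildly anticonservative
(~6.5 % at nominal 5 %), which the calibration tests bound rather
than hide.

## Spatial analyses

Tracks with > 40 % invalid timestamps are rejected outright. Valid
gaps are spline-interpolated (nearest-valid extension at the edges),
then x and y are convolved with a unit-sum 500 ms Hamming kernel
(edge-padded so constants are preserved). Occupancy and β-power maps
use the 24 × 30 grid of 20 px bins; the power map is the power-
weighted histogram divided by the sample-count histogram, hence
exactly invariant to dwell-time rescaling, with never-visited bins
masked. Display smoothing (a 2-bin Gaussian in `betamyg report`) is
cosmetic only; stored values are raw. Speed is net Euclidean
displacement over the 0.5 s window after an event onset divided by
the window (a summed-path alternative is a config switch), reported
in cm/s via the 0.2 cm/px scale; baselines use the 0.5 s before each
cue onset.

## What the simulations do and do not show

Passing tests demonstrate that each stage recovers what was injected
under the stated noise model: 1/f Gaussian background, sinusoidal
bursts with clean tapers, renewal spike trains, waypoint kinematics.
Real recordings add nonstationary artifacts (movement, chewing,
clipping), non-sinusoidal burst waveforms, overlapping oscillators,
and spike-sorting contamination that the simulator deliberately does
not model (no biophysical LFP generation, no volume conduction). The
automated clipping rule is exercised on synthetic plateaus only. Age
differences enter the simulator solely through burst probability —
enough to validate the incidence statistics, not a biological model
of aging. Burst amplitude defaults are chosen for detector
testability, not calibrated to recorded amplitudes, which the source
data do not constrain.

## Problem sizes

Default validation sizes were chosen to keep the full suite and the
acceptance script in the minutes range while leaving Monte-Carlo
error well inside each tolerance: 20 × 10-minute sessions for the
detector, 20,000 draws for the Rayleigh type-I rate, 500 cohorts for
CI coverage, 300 for LR null calibration, 1,000 units for the
rate-modulation null, 10⁴ ISIs for the LV reference values.
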