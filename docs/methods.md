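# Methods

This note documents the generative model behind `scchoice.synthgen`, the
analysis chain, the parameter defaults and how they were calibrated, and
what the synthetic sessions do and do not emulate.

## Task and geometry

Sessions emulate a delayed saccade task under binocular viewing: 500 ms
central fixation, 1,000 ms sensory overlap with the eccentric target,
then a go signal (fixation offset) and a ≤500 ms response window; targets
sit on a 7×3 LED grid (horizontal −30°…+30°, vertical −10°, 0°, +10°, 10°
spacing) and eye position is sampled at 1 kHz. The subject is exotropic:
the fixating eye holds the central LED while the fellow eye deviates
temporally by `h_deviation` (default 30°) plus a small vertical deviation
(default 1°, the grid-friendly end of the 1°–5° range typical of such
subjects). The deviated eye additionally carries a slow random-walk drift
(0.01°/√sample) reflecting its positional instability, and every channel
carries 0.05° white measurement noise.

Saccades are conjugate minimum-jerk movements with the main-sequence
duration 25 ms + 2.2 ms/deg. Endpoints scatter around the target with a
per-component SD of 8% of amplitude (floor 0.25°), shared by both eyes —
without endpoint scatter, simulated amplitudes are ~0.05°-precise and the
amplitude-matching step of the two-target analysis becomes degenerate
(any systematic between-condition amplitude difference, e.g. from the
vertical deviation, is then unmatchable; with realistic scatter matching
retains ~86% of trials). Saccade latency is the race winner's
first-passage time (below), clipped to [80, 280] ms so every trial keeps
a post-saccade epoch for classification.

## Fixation-preference map

With the left eye fixating at 0° and the deviated right eye's line of
sight at +h_deviation, the probability that the right eye acquires a
target at horizontal position h is a sigmoid
P(right) = σ(k·(h − b)), with the border b at the midpoint of the two
lines of sight (plus an offset) and slope k = 0.3/deg. Targets left of
the left eye's line of sight are acquired by the left eye, targets right
of the right eye's by the right eye, and the transition zone between them
is bistable. One-target testing targets are, by experimental selection,
those where behavior is bistable; the generator therefore draws the
per-trial suppression state 50/50 at such targets rather than from the
map (the map remains the behavioral characterization of the whole grid).

## Race model

Each trial, one eye's retinal-error representation is suppressed by the
fraction `suppression` (s, default 0.15). Two accumulators, A (the
recorded neuron's saccade vector) and B (the opposite vector), integrate

    dx = (drive / latency_scale) dt + noise,   drive_A = g_A(1 − s·1[A supp])

with per-trial lognormal gains g (σ = 0.12), latency_scale = 180 ms,
Gaussian increment noise 0.005/√ms and threshold 1. The first accumulator
to cross wins; the winner determines the acquiring eye, and its crossing
time is the saccade latency (median ≈175 ms, right-skewed — an
inverse-Gaussian-like first-passage distribution, so no separate latency
model is needed). At s = 0.15 the suppressed side loses ~85–90% of its
trials; the switch fraction stays near 0.5 because either side is
suppressed with equal probability.

This structure makes the measured sensory suppression a *population
average including the selection effect*: the neuron's visual transient
scales with its own trial drive g_A(1 − s·1[A supp]), so switch trials
(A lost) carry mostly suppressed, lower-gain drives and no-switch trials
mostly unsuppressed, higher-gain drives.

## Visuomotor rate profile

Each cell's firing rate is baseline + visual transient + buildup +
(motor burst on won trials):

* baseline `baseline_hz` (8–16 spikes/s across cells);
* a Gaussian visual transient (σ = 15 ms) peaking `visual_latency_ms`
  (45–55 ms) after target onset, amplitude 240–360 spikes/s scaled by the
  trial's sensory drive;
* a linear buildup ramp from 150 ms after target onset toward saccade
  onset (170–270 spikes/s per s, scaled by the trial gain);
* on won trials, a motor burst (520–760 spikes/s, σ = 20–30 ms) peaking
  15 ms after saccade onset — mid-saccade, as SC bursts do; on lost
  trials no burst, and the buildup collapses exponentially starting
  `divergence_ms` = 125 ms before saccade onset.

**Race coupling (push–pull divergence).** Cells differ in how strongly
their late buildup reflects the resolving competition, via a per-cell
coupling c ~ U(0.1, 1.9). From the divergence time onward the two
outcomes separate in opposite directions with cell-specific strength: on
lost trials the buildup collapses at rate c/τ (τ = 15 ms — the collapse
must run its course within one 25 ms analysis bin for the onset bin to
carry a detectable signature); on won trials the prelude accelerates,
the ramp gaining a factor 1 + 0.4·c·(1 − e^(−Δ/τ)) over the same window,
and the burst's rising flank is broadened by (1 + 1.2c). This
heterogeneity is what the across-cell correlation analysis reads out. It
is not optional: if every cell shared one collapse constant and one rise
shape, both conditions' normalized late-buildup activity would load on
the same per-cell factors (buildup-to-peak ratio, baseline), the
across-cell Pearson r would stay *positive* in every pre-saccadic bin,
and no divergence time could ever be detected. A negative r requires a
cell-level factor entering the two conditions with opposite signs —
exactly what graded engagement in the competition provides: strongly
coupled cells accelerate harder when they win and shed buildup faster
when they lose. Crucially, both arms of the push–pull switch on exactly
at the divergence time, so bins before −125 ms keep their positive
across-cell correlation.

Burst timing matters for the final bin: with the burst peak exactly at
saccade onset, the [−25, 0) bin sits on the normalization maximum, where
estimation noise in the peak pins one condition at 1 and pushes the other
down, anti-correlating the conditions artifactually. Peaking the burst
15 ms into the saccade moves the normalization maximum out of the binned
window and restores the expected all-positive two-target pattern.

## Calibration of the defaults

The race and profile defaults were fixed by requiring that the generative
mechanism express its own configured parameters in the measured,
population-level quantities:

* with s = 0.15, the full pipeline recovers a mean switch-trial visual
  peak reduction of ~15% (12–19% across seeds at 32 cells × 60 trials) —
  the suppression fraction plus the gain-selection effect, diluted by the
  baseline's contribution to the peak and the SDF smoothing;
* with divergence at 125 ms, the earliest significantly negative 25 ms
  bin is the one containing the divergence onset (center −112.5 ms) in
  every seed tested (70 seeds), with earlier bins positive or null.

Rates were placed at the upper end of the physiological range for SC
bursts (peak condition-mean rates of 600–900 spikes/s) because the
across-cell correlation's power is limited by Poisson noise in 25 ms
bins; at these rates the per-bin noise SD is ~2–4% of the normalization
peak, well below the coupling-induced signal.

## Analysis chain: numerical choices

* SDF kernel truncated at ±5σ without renormalization (mass loss < 1e-6);
  spikes binned to the 1 ms output grid before convolution; alignment
  windows are computed on a grid extended by the kernel support so spikes
  just outside the window contribute.
* Saccade detector: 5-sample boxcar, central-difference velocity, 50 deg/s
  detection threshold refined outward to 20 deg/s, minimum duration 10 ms.
  On clean generator trials the onset error is ≤5 ms (median).
* Fixating eye: mean position in the last 200 ms before target onset
  within ±2° of the central LED; acquiring eye: mean position in the last
  150 ms of the trial within 5° of the target; both-eyes or neither-eye
  cases raise typed errors and exclude the trial with a logged reason.
* Amplitude matching (two-target): Welch t-test on the fixating-eye
  conjugate vector amplitude; greedy removal (from the group whose mean is
  farther from the pooled mean, the single trial whose removal maximizes
  p) until p > 0.05 or a group reaches 3 trials (then the cell is
  excluded as unmatchable).
* Visual window (0, 100] ms after target onset (the generator's visual
  latency keeps the transient peak inside it); motor window [−50, +50] ms
  around saccade onset; peaks tie-break to the earliest time and are
  reported with their times.
* Normalization is per alignment over both conditions (target- and
  saccade-aligned traces normalized separately).
* Binned correlation: per-cell mean normalized activity per 25 ms bin,
  Pearson across cells, two-sided p per bin, α = 0.05, uncorrected —
  matching the per-bin bar presentation convention. The across-cell
  sample dimension is isolated behind one function so an across-time
  variant could be swapped in.
* Paired statistics need ≥5 cells (NaN otherwise); the correlation needs
  ≥3; cells need ≥3 analyzable trials per condition.

## Problem sizes

Default study conditions: one-target 32 cells × 60 trials, two-target 40
cells × 40 trials; one session generates and analyzes in a few seconds.
The acceptance script uses the one-target defaults; the replicate checks
in the test suite run 20 seeded two-target replicates per suppression
setting.

## What the synthetic data does not emulate

* No microsaccades, blinks, pursuit, or vergence dynamics; the only eye
  movement is the target-acquiring saccade, so the detector faces an
  easier problem than real traces pose.
* Spiking is inhomogeneous-Poisson: no refractoriness, bursting
  statistics, or spike-sorting contamination.
* The race is stationary within a session: no adaptation, fatigue, or
  reward-history effects on eye choice.
* Receptive-field spatial tuning is not exercised: targets are placed at
  the RF center (`rf_sigma` is carried but not varied), mirroring the
  optimal-LED placement of the experimental design.
* Absolute firing rates are a modeling choice within the SC range, not a
  fit to any recorded cell; passing closed-loop tests shows the analysis
  recovers what the generator encodes, not that the generator reproduces
  any particular recorded neuron.

## Known limitations

* The across-cell negative correlation is produced by the race-coupling
  heterogeneity; other mechanisms (e.g., per-cell divergence-time jitter
  with push–pull inhibition) could produce the same signature and are not
  distinguishable by this analysis.
* The greedy amplitude matcher is locally optimal per step, not globally
  optimal over all removal sets.
* With the default detector, spurious saccades are absent on synthetic
  noise levels; noisier real data would require artifact handling that is
  out of scope here.
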