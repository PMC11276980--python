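# Methods

This note documents the models, measurement definitions, numerical choices
and known limitations behind `slicephys`. Units throughout: seconds for
time, mV for voltage, pA for current, MΩ for resistance; LFP amplitudes are
arbitrary units expressed relative to the noise standard deviation.

## LFP event detection

**Pipeline.** `preprocess` applies an 8th-order lowpass Butterworth with
cutoff `target_rate/2` (default 100 Hz) and decimates to `target_rate`
(default 200 Hz). Filtering is zero-phase (forward–backward), so event
onsets are not delayed; the effective magnitude response is the squared
Butterworth magnitude `(1 + (f/fc)^(2n))^(-1)`. The forward–backward pass
uses mirror ("even") edge extension with a pad of 100 output-sample periods:
the default odd extension forces the filtered output through the raw edge
sample, which for a lowpassed noisy trace produces a startup spike several
times the filtered noise SD — large enough to cross the detection threshold
and fabricate an event at t = 0.

**Threshold.** The signal is median-subtracted over the whole recording and
rectified (absolute value by default; positive- or negative-only polarities
are available because electrode polarity is arbitrary). The threshold is the
99th percentile of the rectified amplitude distribution, computed once per
recording with the linear-interpolation percentile convention. Because the
threshold is a quantile of the recording's own amplitudes, detection is
exactly invariant to positive rescaling. The percentile presumes
epileptiform events occupy roughly the top ~1% of samples, which holds for
discharge rates of ~0.5–2 events/s at a 200 Hz analysis rate; for much
sparser activity a higher percentile is appropriate, and the value is
exposed in `DetectionConfig`. The threshold is deliberately not recomputed
per segment; recordings with strong baseline drift should enable the
optional detrending or split the recording.

**Event emission.** Scanning the rectified trace, each sample strictly above
threshold emits a uEE at that sample's time unless it falls within the
50 ms lockout after the previously emitted event. The lockout restarts only
from emitted events (non-retriggerable): later suprathreshold samples inside
the window are ignored and do not extend it. An exhaustive per-sample
brute-force implementation of the same rule serves as the test oracle.

**Ictal segmentation.** Single-linkage clustering in time: maximal runs of
events with successive gaps ≤ `max_gap` (default 1.0 s) and at least
`min_events` (default 5) members become ictal discharges; every other event
is interictal. The 1 s gap sits between the two IEI modes characteristic of
4-AP slice activity (~0.3 s within discharges, ~2 s between interictal
events) and cleanly separates them when the interictal rate is near
0.5 events/s. At interictal rates ≳ 1/`max_gap` the background itself forms
long runs and the rule, by construction, merges background into discharges —
this is a property of any gap-based rule, and the reason the
cluster-recovery tests run at the 2 s-mode regime while the detector
false-positive bound is evaluated at ~1.5 events/s (where it does not
involve segmentation).

**IEI modes.** Intervals are successive onset differences. The histogram
uses log-spaced bins; modes are local maxima of a Gaussian kernel density on
the log10-interval axis (bandwidth in decades, default 0.05), reported
largest peak first. The log axis matters: for a gamma-interval renewal
process the density of log-intervals peaks exactly at the mean interval
(the x·f(x) mode of a gamma is kθ), so the interictal mode estimates
1/rate without the shape-dependent bias of a linear-axis mode. A perfectly
periodic train (zero spread) short-circuits to a single mode at the median.

**Spectrogram.** Complex Morlet continuous wavelet transform
(pywavelets `cmor1.5-1.0`); scales are chosen so each requested frequency
equals the wavelet centre frequency, and power is the squared coefficient
magnitude on the signal's own time base.

**Scoring against ground truth.** A detection matches a planted onset if it
lies within ±25 ms (half the lockout). Recall is the fraction of planted
onsets matched; the false-positive fraction is the fraction of detections
matching no planted onset.

## Synthetic LFP generator

Interictal onsets follow a gamma renewal process with mean interval
1/`interictal_rate` and a 0.1 s floor. The default shape parameter is 8:
narrow enough that, at the 2 s-mode regime, fewer than ~0.2% of background
gaps fall under the 1 s segmentation gap (a shape of 4 leaves ~14% of gaps
below 1 s, which generates spurious run-of-five "discharges" at a rate
incompatible with exact cluster-count recovery). The log-density mode sits
at the mean for any shape, so the choice does not bias the IEI mode.

Each event is a biphasic transient: a sharp depolarizing half-sine lobe
(width 10 ms, peak `interictal_amplitude` × noise SD, default 8) followed by
a shallow opposite lobe (3× wider, one tenth the amplitude). The slow lobe
ends inside the 50 ms lockout and stays well below threshold scale after
filtering; an early draft with a larger slow lobe produced lockout-expiry
retriggers, which is worth knowing for anyone replacing the waveform.

Ictal clusters are runs of `cluster_n_events` (default 30) events spaced
`intra_cluster_interval` (default 0.3 s) ± 20% uniform jitter, placed
uniformly at random subject to ≥ 10 s separation from each other and 5 s
from the edges; placement failure raises rather than overlapping. Noise is
white Gaussian by default; a pink+white option mixes equal powers of
1/f-shaped and white noise. All draws come from one seeded generator, so a
config is bit-reproducible.

What the generator does not emulate: electrode drift, line interference,
state-dependent waveform changes within a discharge, and propagation between
simultaneously recorded channels. Passing detection tests therefore shows
the algorithmic chain is correct under the stated statistical structure, not
that it is robust to every artifact of real recordings.

## Synthetic current-clamp cells

The subthreshold membrane is an exact single-exponential RC response toward
`rmp + I·r_in` with time constant `tau_m`, rendered analytically (so
noiseless parameter recovery is limited only by the analysis, not by solver
error). Spike timing uses an adaptive integrate-and-fire rule solved in
closed form between spikes: the planted `rheobase` is authoritative — the
effective crossing voltage is `rmp + (rheobase − 1 pA)·r_in`, which makes
the measured rheobase exact on any current grid containing it. Each spike
increments an adaptation current by 5 pA × `adaptation_strength` (decay
time constant 1 s, frozen within each interval), lengthening successive
ISIs; the ground truth for adaptation is the emitted ISI sequence itself.
Above `block_current`, spike emission stops 200 ms into the step and the
membrane holds a plateau 2 mV below threshold (a phenomenological
depolarizing block — the measurand is the block current, not its
mechanism).

The action-potential waveform is a stereotyped template pasted at each
crossing: a 3 mV/ms foot from the crossing voltage to `spike_threshold`
(below the 5 mV/ms detection criterion, so the measured threshold lands at
the intended voltage), a raised-cosine upstroke (0.58 ms) to
`threshold + spike_amplitude`, a quarter-sine downstroke (3.2 ms) to the
fAHP trough, a cosine ADP bump, a descent to the mAHP trough
(`mahp_time` = 65 ms after the fAHP) and a 15 ms recovery, after which the
RC recharge resumes. Template features have closed forms, and the ground
truth records them *operationally*: the planted fAHP is the voltage at the
point where the downstroke slows below 5 mV/ms (slightly above the
geometric trough), because that is the definition the analysis applies.
The AHP portion of the template is obligatory, which caps sustained firing
near 1/(template length) ≈ 11–15 Hz — adequate because waveform features
are defined at rheobase, where ISIs are long. The generator does not model
conductances, channel noise, Ih sag, or spike-height accommodation.

## Patch-clamp analysis numerics

* Spike onsets: centred-difference dV/dt upward crossing of 5 mV/ms,
  validated by a peak ≥ 20 mV above the onset voltage within 5 ms; onsets
  ≥ 1 ms apart. `smooth_hz` (recommended 2 kHz for noisy recordings, off by
  default) lowpasses the trace before differentiation; with ~0.2 mV noise at
  25–50 kHz the raw derivative noise would otherwise swamp the criterion.
* Passive properties: RMP is the pre-step mean of the zero-current sweep
  (pre-step baseline mean if none); input resistance is the OLS slope of
  steady-state deflection (mean over the last 20% of the step) versus
  current over spike-free sweeps; τ is fitted by nonlinear least squares to
  `V∞ + (V0 − V∞)e^(−t/τ)` over the onset of the largest hyperpolarizing
  response, the window spanning 5× an initial log-linear estimate.
* AP features: amplitude, rise time and half-width use linear interpolation
  of level crossings; the fAHP point interpolates the |dV/dt| = 5 mV/ms
  crossing between samples (a whole-sample convention biases the fAHP deep
  by up to slope × sample period). The mAHP is the post-fAHP minimum in the
  window (to the next onset or +150 ms); if the minimum sits on the window
  edge the AHP features are reported missing rather than guessed, and a
  window ending at the spike peak raises an error.
* Firing pattern: rates are spike count / step duration. Depolarizing block
  is operationalized as the smallest current above the maximal-rate current
  whose rate falls below 50% of the maximum while the mean voltage over the
  last third of the step stays within 5 mV of spike threshold; both knobs
  are arguments. Adaptation ratios are computed at the next available
  amplitude above rheobase and require ≥ 3 spikes (otherwise missing); ISIs
  are differenced in integer sample counts so evenly spaced spikes give
  ratios of exactly 1. "Hump amplitude" has no standard definition; it is
  implemented as max(V in the first 100 ms of the step) minus the
  steady-state mean on the largest spike-free depolarizing sweep, and should
  be read as an interpretation.

## Evoked-EPSC analysis

Responses are inward by convention (configurable). Per stimulus: 1 ms
post-stimulus blank (artifact), baseline = mean over the 1 ms before the
stimulus (per-pulse local baseline compensates superposition on the previous
decay; a global pre-train baseline is available by flag), peak = extremum up
to just before the next stimulus (last pulse: `decay_window`). Response
presence is judged by a 2 ms post-stimulus mean against 3× the pre-train SD
— a per-sample extremum would exceed 3 SD on pure noise almost surely.
With instantaneous-rise responses the 1 ms blank costs a factor
`e^(−1 ms/τ)` on absolute amplitudes (2.5% at τ = 40 ms); normalized
vectors and the paired-pulse ratio are unaffected. The generator snaps
stimulus times to the sample grid, as a DAQ-clocked stimulator does.

## Statistical screen

Modified z-scores `M_i = 0.6745 (x_i − median) / MAD`, two-tailed flag at
|M| > 3.5 (cutoff exposed). MAD = 0 raises rather than silently switching
scale estimates; the screen is single-pass, and the documented usage after
removing a flagged point is to recompute. Group comparison delegates to
scipy: a one-sample KS statistic against a normal with sample-estimated
parameters (estimating the parameters makes the nominal p-value
conservative — the Lilliefors caveat — so treat it as a check, not an exact
test) and the unpaired equal-variance t test, reported with mean ± SEM.

## Problem sizes

The test suite verifies the detector's false-positive bound on ten 1 h
recordings at 10 kHz (the full acquisition-scale condition), structure
recovery on ten 600 s recordings at 5 kHz, and patch recovery on twenty
synthetic cells at 25 kHz with 36-sweep families — sizes chosen so the whole
suite runs in a few minutes on one CPU while keeping every recording at the
duration and rates the measurements assume.
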