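# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Synthetic sessions

A session is an explicit linear forward model: `data = mixing @ sources`,
channels × samples, in microvolts, with planted channel faults overwriting
rows afterwards.  Keeping every stochastic term inside the source matrix
(including per-channel sensor noise) makes the reconstruction identity exact
and lets recovery tests compare against the generating truth.

**Stimulus schedule.**  `n_chirp` chirp onsets separated by silences drawn
Uniform[0.6 s, 2.5 s] ("at least 0.6–2.5 s" is read as that stated range;
no distribution beyond uniform is assumed).  An equal number of 0.5 s silent
control epochs is placed uniformly inside the silences by stick-breaking,
disjoint from every chirp epoch and from each other.  Placement is exact or
fails loudly with the slot deficit.

**Evoked source.**  Each trial adds an amplitude- and latency-jittered copy
of the canonical template (below) at its onset.  Jitter defaults — 10 ms
latency SD, 20 % amplitude SD — are physiologically plausible single-trial
variabilities and configurable (`latency_jitter_s`, `amplitude_jitter`).

**Canonical ERP template.**  Each wave is a third-order gamma kernel
`h(t; τ) ∝ t² e^(−t/τ)` normalized to unit peak (continuous peak at
`t = 2τ`): the early wave is negative with τ = 50 ms (N100, peak 100 ms),
the late wave positive with τ = 150 ms (P300, peak 300 ms).  Because the
two waves overlap, the extrema of their *sum* sit slightly off the
single-wave latencies (the sampled default template has its most negative
sample at ~77 ms and its most positive at ~360 ms); tests pin the
single-wave peaks exactly and the summed extrema against a dense-sampling
oracle.

**Background and artifacts.**  1/f processes plus a narrowband 10 Hz alpha
source with smooth random topographies; combined background RMS is fixed at
10 µV at the channel where the (fronto-central) evoked topography peaks.
`erp_snr` is the ratio of within-epoch evoked RMS to that background RMS at
that channel, so the evoked contribution scales linearly with `erp_snr`;
the default 0.2 yields a ≈5 µV best-channel peak, a realistic single-trial
regime.  `erp_snr=inf` is the noise-free limit (background, artifacts and
sensor noise all zero).  Artifacts: frontal blink transients, two focal
20–80 Hz muscle-burst sources, a focal low-frequency (3–8 Hz) vibration
component, and an optional mains sinusoid.  The `on` regime raises rates
and amplitudes (150 µV blinks, 100 µV RMS muscle, 20 µV RMS vibration) to a
severe-but-recordable level: some channels cross the 100 µV rejection rule,
most survive, mirroring in-operation recordings.  Sensor noise is 0.7 µV
RMS per channel, the noise floor quoted for dry active-electrode hardware.

**What the generator does not emulate:** no biophysical head model (the
topographies are smooth random vectors, not leadfields), no
attention-dependent evoked attenuation beyond the scalar `erp_snr`, no
non-stationary artifact statistics (each artifact class is homogeneous over
a session).  Passing tests therefore demonstrate correctness of the
algorithms under a controlled mixing model — not performance claims about
any particular real recording.

## Preprocessing

**Filter.**  Windowed-sinc (Hamming) linear-phase FIR, order 496, band
2–30 Hz at 300 Hz; even order gives an integer 248-sample group delay.
Offline application is forward–backward (zero net phase, reflection
padding), so the effective magnitude response is squared; a causal path is
a one-line change (`scipy.signal.lfilter` on the same taps) for latency
studies.  Signals shorter than three filter lengths are rejected rather
than filtered with dominant edge transients.

**Bad channels.**  The four rules run on band-passed data (rejection is
listed after filtering; the order is otherwise unstated).  The "robust
estimate from other channels" is realized as per-window (1 s) ridge
regression of each channel on all others (ridge weight 1e-3 × mean channel
variance), median correlation over windows; the median across windows
supplies the robustness that a RANSAC variant would.  The line-noise score
is RMS(above 45 Hz)/RMS(below 45 Hz), z-scored across channels — 45 Hz
splits the EEG band from both 50 and 60 Hz mains at fs = 300.

**ASR.**  Calibration uses windows whose per-channel RMS robust z-scores
(median/MAD across 1 s windows) lie within (−3.5, 5.5) for ≥ 93.75 % of
channels, requiring ≥ 30 s of clean data.  The robust covariance is the
elementwise median of 0.5 s window covariances.  The elementwise median of
PSD matrices can leave the PSD cone, so eigenvalues are clipped at
1e-9 × the largest before taking the principal square root; a channel with
no variance at all raises an error naming it.  Thresholds are
mean + 5·SD (cutoff k = 5, the method's historical default; k is exposed
because later toolbox versions default to 20) of windowed RMS per
calibration eigendirection.  Processing slides 0.5 s windows at 0.25 s
steps, flags window eigendirections whose RMS exceeds the calibration
thresholds mapped into the window basis, reconstructs with
`R = M · pinv(keep ∘ (VᵀM)) · Vᵀ` (identity when nothing is flagged), and
blends overlaps with a raised-cosine (Hann) ramp.

## ICA

Extended infomax: sphere to unit covariance, then natural-gradient block
updates (block 256, initial rate 0.001/ln C) with a ±1 kurtosis-sign matrix
re-estimated each pass from 6 000 random samples; the learning rate anneals
by 0.98 whenever the update direction turns more than 60°; stop at weight
change < 1e-6 or 512 passes (non-convergence sets a flag and warns — the
decomposition is still usable).  No PCA reduction: component count equals
retained channels.  Components are ordered by descending mean projected
variance (mean squared mixing column × activation variance).

Manual component inspection is replaced by template correlation: each
component's chirp-locked average (training chirps only) is correlated with
the canonical template; the top k = 2 components with |r| ≥ 0.4 are kept,
matching the two components per condition that visual inspection selects.
The template is passed through the same band-pass as the data before
correlating — the 2 Hz high-pass edge reshapes the slow positive wave
enough to cap the attainable correlation near 0.76 otherwise.  All scores
are absolute-valued (ICA sign indeterminacy), and an empty selection falls
back to all components with a warning.

## Kalman ERP estimation

Each wave is a third-order cascade with repeated pole
`a = exp(−1/(fs·τ))`, τ = peak/2 (the continuous argmax of `t²e^(−t/τ)` is
2τ).  The realization is impulse-invariant: a Jordan-block transition with
input vector `g·(a, 3a², 2a³)` and first-state readout makes the noiseless
unit-impulse response exactly `g·n²·aⁿ` — the sampled continuous kernel —
so the discrete peak falls exactly on sample 30 (100 ms) and 90 (300 ms) at
300 Hz, normalized to unit magnitude with signs encoding the N100
negativity and P300 positivity.  (A literal chain of three delay-coupled
first-order sections would add transport delay and shift the peak to
~107 ms.)

The 6-state filter is standard and causal: `Q = q·I` white state noise,
scalar measurement noise `R = 0.001·q` (the estimate trusts the
measurements; only the ratio matters for the gains, so q = 1), prior
`P₀ = 10·I` for a fast burn-in, input impulse at every trial onset — chirp
and silent alike, since labels are unknown at test time; discrimination is
left to the measurements.  The covariance recursion is data-independent, so
it is iterated exactly until it reaches its steady state (verified against
the discrete algebraic Riccati solution) and the converged gain is reused;
a stack of traces (all channels, or all selected components) shares one
gain sequence.  No smoothing pass and no Q/R estimation: the filter is
deliberately instantaneous with a fixed ratio.

## Classification and inference

LSPC fits, per class, `θ_y = (GᵀG/n + λI)⁻¹ Gᵀ b_y/n` with the full
training Gram of Gaussian kernels — one dense solve, no iteration.
Posteriors are rectified at zero and normalized (uniform if all scores are
non-positive); prediction ties break toward *silent*, the conservative
choice that avoids false alarms (configurable).  The hyperparameter grid —
σ ∈ median pairwise distance × {0.1, 0.3, 1, 3, 10},
λ ∈ {1e-3, 1e-2, 1e-1, 1} — is searched by randomized stratified 10-fold
CV on validation accuracy; ties prefer the smaller σ, then the larger λ
(the smoother model).  Repeated evaluation re-randomizes the folds each of
100 repeats; the permutation test retrains on shuffled *training* labels
(the stricter reading: the null model goes through the same selection
pipeline) and uses the add-one-corrected p.  d′ clips hit/false-alarm rates
to [1/(2N), 1−1/(2N)].  The Wilcoxon signed-rank comparison drops zero
differences, uses midranks for ties, an exact convolution null for n ≤ 25
and a tie- and continuity-corrected normal approximation above.

## Pipeline contracts

The chronological split is per label (earliest ⌈0.75·n⌉ events of each
class train), which preserves the 150/150 + 50/50 counts even when labels
interleave unevenly; the training span for fitting is every sample before
the first test onset.  All cleaning statistics — filter output used for
detection, bad-channel list, ASR model, ICA weights, component selection —
are computed from that span alone and applied unchanged to the rest, and a
test verifies that deleting the test span changes none of the fitted
parameters.  All randomness flows from one master seed through named
substreams (ICA init, fold assignment, permutations, nested re-runs), so
reports are byte-identical across runs.

## Problem sizes

The shipped tests and examples run at 16 channels and ≈5-minute sessions
with 200 + 200 trials, 3–25 evaluation repeats and 100 permutations — large
enough for every protocol identity to be exact and every recovery property
to be measurable, while a full analysis stays in the tens of seconds on one
core.  All sizes scale through `SessionConfig`/`PipelineConfig`.

## Known limitations

- No EDF export (no writer library is declared as a dependency); recordings
  round-trip through `.npz`, EDF input is read via `mne` when installed.
- ASR here implements the covariance-median/eigenthreshold form with a
  Euclidean (elementwise) median; geometric-median and RANSAC variants of
  the calibration statistics are out of scope.
- The permutation and nested-comparison machinery assumes balanced classes
  (the identity accuracy = 1 − (FPR+FNR)/2 is also only exact then).
- Kalman filtering models every trace with the same two-wave dynamical
  model; non-auditory components are filtered with a mismatched model by
  construction.
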