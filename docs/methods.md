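# Methods

This note documents the models, conventions and numerical choices behind
`microspike`: a detection-and-sorting pipeline for single-electrode
C-fiber microneurography, plus the synthetic-recording generator used as
its test substrate.

## The problem

Microneurography records extracellular voltage from a single tungsten
microelectrode near a peripheral nerve fascicle in awake humans.  Several
C-fibers contribute spikes to the same channel; their waveforms are small
(SNR roughly 3–12), mutually similar, and drift slowly over long sessions.
Classic array-based sorters rely on spatial information that a single
channel does not have.  What the preparation *does* offer is electrical
stimulation: a background pulse every 4 s evokes exactly one time-locked
spike per activated fiber, so each fiber appears as a vertical *track* of
near-constant latency in a stimulus-aligned waterfall plot.  Two
consequences drive the design:

1. **Labels for free.** Background-evoked spikes carry reliable fiber
   identities, giving per-recording training data for supervised sorting.
2. **Activity leaves a latency signature.** A C-fiber that fired between
   two background pulses conducts more slowly for a while
   (activity-dependent slowing, ADS), so its *next* background response is
   delayed.  A latency jump therefore implicates the preceding interval as
   one containing extra activity.

## Segmentation and latency conventions

All event times are absolute seconds from recording start; sample indices
are 0-based; windows are half-open `[start, end)`.  Marking-mode
segmentation cuts only at background onsets; ground-truth-mode cuts before
every pulse, yielding variable-length windows so that every electrically
evoked spike is time-locked to its own stimulus.  Latency is
`(spike_time − defining_stimulus_onset) × 1000` ms.  A spike preceding the
first stimulus is flagged (`window_index = −1`, NaN latency), never
dropped.  Within one track, a spike is background-evoked iff the interval
to the previous spike is ≥ 3.8 s (just under the 4 s stimulation period);
the first spike counts as background-evoked, since the first response in
these protocols is always to a background pulse.

## Waveforms, templates, quality

Waveforms are 30 samples (3 ms at 10 kHz), aligned on the sample minimizing
the forward first difference of the raw trace — the steepest downward
slope — searched within ±1 ms of the nominal spike time.  No smoothing is
applied before differencing; C-fiber spikes at 10 kHz are 1–2 ms wide and
the discrete difference is adequate.  Templates are element-wise means;
template amplitude is the maximum absolute value (thresholds are quoted as
single positive µV values, so peak-to-peak would be the wrong scale).

SNR is the template amplitude of the highest-amplitude track divided by a
robust noise SD, `MAD/0.6745`, measured on a 40 ms segment ending 1.5 ms
before the first evoked spike.  It is computed on the stored trace (which
in practice is already band-passed by the acquisition chain).  The drift
check splits a track's waveforms into three contiguous temporal thirds
(remainder samples join the earliest subsets — `numpy.array_split` order)
and reports the maximal pairwise RMSE between the three templates.
Pairwise template distances (MSE/RMSE/MAE) over background-evoked
templates, with the off-diagonal minimum retained, serve as a pre-sorting
separability index: near-identical templates predict poor sorting.

## Detection

The detector is deliberately permissive and recall-oriented; precision is
recovered later by the classifier:

* **Threshold**: background-evoked peak amplitudes of the track of
  interest are sorted ascending; the smallest is suggested.  If their
  coefficient of variation exceeds 0.3 the suggestion is flagged and a
  manual threshold is expected.  Polarity is a switch (positive default;
  external sorters often threshold on negative peaks).
* **Gating**: one latency per marking window (NaN where the track did not
  respond).  Window *k* is searched iff the next responded window's
  latency exceeds a running baseline by > 0.9 ms — the minimal latency
  deviation observed without additional stimulation.  The baseline is the
  median of the last 5 latencies that did not themselves jump, which
  tolerates slow latency drift while excluding post-burst elevated values.
  The first responded latency seeds the baseline.  Windows without a
  response are searched and marked *uncertain*.  This attribution (flag
  the window *preceding* the delayed response) follows ADS causality.
* **Peaks**: local extrema via `scipy.signal.find_peaks` with the
  threshold as height and a 1 ms minimum separation (well under the ≥5 ms
  single-fiber refractory bound implied by <200 Hz firing, but allowing
  distinct fibers to fire closer).  Peaks within 100 ms of a window's
  stimulus onset are discarded as stimulation artifacts.  Raising the
  threshold can only remove peaks, so detection counts are monotone
  non-increasing in the threshold.

## Feature sets

Three per-waveform vectors feed the classifiers: the 30 raw samples
(`w_raw`); a 23-descriptor shape/phase/distribution set (`spdf`) over the
waveform and its first and second differences (extremum amplitudes and
positions, pre/post-peak slopes, half-width, peak-to-peak amplitude and
duration, energy, absolute area, derivative zero-crossing counts,
standardized 3rd/4th moments); and a 3-coordinate projection of it
(`spdf_fv3`), by default {first-difference negative peak, peak-to-peak
amplitude, half-width}, configurable because no canonical triple exists.
The 23-descriptor list is this package's frozen definition — the exact
descriptor inventory of the cited SPDF lineage is not fully specified
anywhere, so the set is versioned here and pinned by golden-vector tests;
downstream code depends only on the vector length.

## Sorting

Three classifier kinds: a one-class SVM (novelty detector trained only on
the interest track's background spikes), a multi-class RBF SVM, and
gradient-boosted trees (XGBoost, `tree_method="exact"`: training sets are
tens to hundreds of spikes, where histogram binning can misplace splits).
Margin classifiers see standardized features with the scaler fit on
training folds only; trees take raw features.

Hyperparameters are tuned by seeded random search over frozen spaces —
SVM: C ∈ log[1e−2, 1e3], γ ∈ log[1e−4, 1e1]; one-class: ν ∈ [0.01, 0.5],
same γ; trees: depth ∈ [2, 8], learning rate ∈ log[0.01, 0.3], estimators
∈ [50, 500] — scored by mean F1 across 5 stratified folds shared between
trials.  F1 is one-vs-rest for the track of interest (macro-averaging is
available behind a flag); the evaluation focus throughout is the fiber of
interest.  `select_model` runs the full 3 × 3 grid and returns the argmax
with the grid attached; exact ties resolve as w_raw > spdf > spdf_fv3 and
xgboost > svm > one_class_svm, and are logged.  The winner is retrained on
all background spikes and applied to the detected spikes; one-class
outliers are labeled `"rejected"`.  Folds are stratified without temporal
blocking (no blocking rule is defined for these data) — a mild leakage
caveat when waveforms drift.

Defaults: `cv_optimize` runs 50 trials; the pipeline default is 20 and the
shipped end-to-end experiments use 12–15, which on these small training
sets already saturates the grid.

## Evaluation

Timestamp matching is greedy nearest-first one-to-one within a tolerance
(2 ms for detection).  Greedy and optimal bipartite matching differ only
in pathological clusters; tests quantify the divergence against an
exhaustive assignment oracle (≥95% exact agreement on random ≤20-event
instances, greedy never exceeding the optimum).  Matched predictions are
TP, unmatched predictions FP, unmatched truth FN.  TN has no natural event
universe in detection; the convention here is the number of searched
windows containing neither a truth spike nor a detection — documented as
convention, not ground truth.  Undefined ratios (0/0) are reported as
`None`, never coerced to 0 or 1.  Sorting confusion is fiber-of-interest:
TP requires both a ±tol match to a truth spike of the track *and* the
track's label.

Cross-system comparison utilities implement per-stimulus piecewise-constant
offset correction (each external timestamp shifted by its nearest
preceding anchor's offset), exclusion of events within 10 ms after any
stimulus onset (exclusion first, then ±3 ms matching), and firing measures:
instantaneous frequency as inverse inter-spike interval, spike counts in
4 s bins, and flagging of intervals implying ≥200 Hz — beyond plausible
C-fiber rates — including the infinite rate of duplicate timestamps.

## The simulator

The generator emulates the ground-truth stimulation protocol, not a
biophysical axon:

* **Stimuli**: background pulses every 4 s; per interval a drawn number of
  extra pulses at a drawn frequency, starting 0.3 s after the background
  pulse, with the last extra pulse at least 1 s before the next background
  pulse.
* **Fibers**: each responds to each pulse with probability
  `response_prob` (presets: 0.95), after
  `base_latency + slowing + jitter`.  Slowing gains `ads_delta` ms per
  emitted spike and decays as `exp(−Δt/ads_tau)` (defaults 2 ms and 60 s —
  chosen so a 5-spike burst shifts the next background latency well above
  the 0.9 ms gating threshold, consistent with slowing that scales with
  preceding spike count).  Latency jitter is 0.1 ms SD; refractoriness of
  5 ms enforces the <200 Hz bound.  Base latencies are spread over
  150–350 ms — plausible C-fiber conduction delays, not verified against
  published values.
* **Waveforms**: a difference-of-Gaussians biphasic kernel (positive lobe
  σ = 0.25 × width, trough 0.9 relative at 0.45 × width delay; ~0.9 ms
  FWHM for the default 1.5 ms width).  The sharp downstroke makes
  first-difference alignment stable within ±1–2 samples under unit noise.
  Peak amplitude jitters log-normally with 5% SD.
* **Noise**: white Gaussian filtered to 500–1000 Hz with a 4th-order
  Butterworth band-pass (matching the acquisition chain), then rescaled so
  its SD equals `noise_sd` exactly; a target SNR *s* is realized by
  setting the interest fiber's amplitude to `s × noise_sd`.  Measured
  (template/MAD) SNR comes out ~2–3% below the target because alignment
  jitter slightly smears the template mean — within the 10% recovery
  tolerance the tests enforce.
* **Presets** `A1_like … A6_like, AC_like` mirror the study regimes'
  fiber counts (2, 2, 2, 3, 5, 3, 2), extra-pulse ranges and target SNRs
  (9.5, 6.8, 5.5, 3.1, 6.8, 5.5, 11.8).  Secondary fibers take descending
  amplitude ratios (0.65, 0.5, 0.42, 0.36) and distinct widths.  Preset
  duration defaults to 120 s; the shipped experiments use 60–100 s
  recordings (15–25 background pulses, i.e. ~15–25 labeled spikes per
  fiber), which is ample for the 5-fold CV grid while keeping a full
  10-seed experiment under a minute per condition.

What the generator does **not** emulate: stimulation artifacts (blanking
is still applied, but nothing is there to remove), waveform shape drift
over time, overlapping-spike superposition artifacts beyond linear
summation, spontaneous (non-evoked) firing, and non-Gaussian noise such as
movement artifacts or mains interference.  Passing tests therefore
demonstrate correctness of the pipeline's logic under controlled
conditions, not performance on arbitrary laboratory data.

## Degenerate inputs and tie-breaks

Flat alignment regions raise a degenerate-signal error; zero-MAD noise
segments likewise.  Track-of-interest amplitude ties resolve
lexicographically with a warning.  Empty flagged-window sets produce an
empty detection result with a warning, not an error.  Recordings whose
interest track has fewer than 10 background spikes cannot run the
one-class grid cell and are rejected with an insufficient-data error
(use ≥ 60 s of stimulation).

## Known limitations

* Gating can over-flag windows during the slow post-burst latency
  recovery; this costs detection precision only (the criterion is that
  flagged ⊇ truly active windows).
* Sustained extra activity drives the additive ADS state toward a high
  equilibrium (no saturation term); latencies remain well inside the 4 s
  window under the preset regimes, but extreme configurations could
  violate that.
* The multi-class sorters have no noise class; detected noise events are
  absorbed by whichever track is nearest in feature space, and only
  fiber-of-interest assignment is evaluated.
* One recording-wide threshold and a single track of interest per run,
  mirroring the original workflow.
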