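# Methods

`honpipe` analyses ensemble calcium imaging of hypocretin/orexin neurons
(HONs) recorded around self-paced locomotion and sensory stimulation,
and ships a forward simulator that generates recordings with the same
statistical structure plus full ground truth, so that every stage of
the analysis can be validated end to end without any experimental data.
This note documents the model behind the simulator, the analysis rules,
the parameters that matter, and the design choices made where the
procedure was genuinely open.

## The analysis chain

Raw fluorescence is processed in a fixed order:

1. **Extraction** (`traces.extract_traces`): `F_raw` is the mean pixel
   intensity inside each ROI; `F_np` is the mean over a ring of pixels
   at Chebyshev (square) distance 3–6 px outside the ROI outline,
   excluding pixels belonging to any ROI. The square-ring convention is
   the common miniscope one; the distance metric is a choice, since
   "third to sixth nearest pixels" does not name one. A cell whose ring
   is empty in a crowded field falls back to the frame background mean
   and is logged.
2. **Neuropil subtraction** (`neuropil_correct`): `F_raw − F_np`,
   elementwise, with no scaling coefficient (r = 1).
3. **Smoothing** (`moving_average`): centred boxcar, edge-truncated.
   Three frames for classification inputs; 5 or 50 samples for
   photometry. Centred windows avoid phase lag in onset estimates,
   at the price of leaking a signal up to half a window backwards in
   time — the onset tests account for that half-width.
4. **ΔF/F₀** (`dff`): three baseline estimators — a 100 s moving median
   (miniscope bleach correction), a 240 s moving mean (photometry), and
   a 2 s pre-event mean (stimulus-locked photometry). Moving windows
   are centred and truncated. `F₀ ≤ 0` anywhere is an error naming the
   sample.
5. **Z-scoring** (`zscore`): per cell over the full record; hunger-state
   sessions can be concatenated and z-scored jointly so amplitudes are
   comparable across states.

Time is in seconds, frame timestamps mark frame starts, and all windows
are half-open `[start, end)`. The σ used everywhere is the population
standard deviation (denominator *n*).

## Subtype classification

Cells are classified from the bout-averaged z-scored trace aligned to
locomotion onset (locomotion = speed > 1 cm/s; sub-threshold gaps
< 0.5 s merged, runs < 0.5 s dropped — defaults that stop sensor noise
from fragmenting bouts). Baseline mean and σ come from 10–6 s before
onset; extrema are searched 6 s before to 16 s after onset; the
max/min responses are 1 s means centred on the extrema (truncated at
the search-window edges). A cell with only `max > baseline + 2σ` is ON,
only `min < baseline − 2σ` is OFF, both with max first is up-down, both
with min first is down-up, neither is non-modulated. Cells with fewer
than 3 usable bouts are reported unclassifiable rather than forced.

Onset time is the first sample deviating ≥ 1σ from baseline that stays
deviated for ≥ 2 s, searched in the same extrema window. The deviation
direction is tied to the subtype's initial phase (upward for
ON/up-down, downward for OFF/down-up): suppressed subtypes only deviate
downward at first, so a signed rule is the only one that yields onsets
for them. The active-frame fraction uses a whole-recording mean + 2σ
cutoff to define active frames and counts the share that falls within
bouts padded by ±3 s.

An independent brute-force re-evaluation of the verbal rule (plain
loops, no shared code) agrees with `classify_cell` on 1,000 random
smooth traces with zero disagreements (`tests/test_acceptance.py`).

## Decoding and prediction

- **Online prediction variable**: mean activity of selected ON cells
  (early onset, active-move fraction ≥ 0.9) over a trailing 3-frame
  window — computable in real time — thresholded at 2 s.d. of the
  variable. Frame detection rate, false-positive rate and per-bout lead
  times are measured against bout spans padded ±3 s; a bout counts as
  predicted when a crossing occurs within 5 s before onset with no
  intervening movement (the window comfortably covers lead times of a
  second or two).
- **Population decoding** (`svm_decode`): linear SVM with fixed C = 1,
  8-fold stratified cross-validation repeated 10 times with re-drawn
  folds (80 analyses), on balanced sets of 20 s movement epochs
  (centred on bout onsets) and stationary epochs drawn ≥ 5 s away from
  any locomotion. Features are per-cell means in 0.8 s windows;
  features are standardised inside training folds only, a leakage
  guard. Permuting epoch labels before every repeat gives the empirical
  chance distribution. Per-window window-mean features were chosen over
  concatenated frames; the window-mean variant is the natural reading
  of accuracy reported per 800 ms bin.
- **ROC time courses** (`roc_auc_timecourse`): per time sample, the
  predictor is the subtype-mean activity per trial and the AUC is the
  Mann–Whitney probability that a movement trial exceeds a stationary
  trial. For stimulus-aligned analyses, moving trials can be censored
  from bins at or after their locomotion onset so the AUC reflects
  strictly pre-movement information. AUC is reported on the 0–1 scale.

## Sensory responses

Response amplitude is the mean z signal 1–4 s after stimulus onset,
averaged over eligible trials. A trial is eligible when no locomotion
bout overlaps the span from 10 s before to 5 s after the stimulus: the
forward guard covers the scoring window; the backward guard exists
because the reporter decay tail of a bout ending just before the
stimulus contaminates the scoring window for most movement-modulated
cells at once, which would correlate false positives across the
ensemble.

The null stimulus (a tone that drives no response) calibrates
meaningfulness: the global min/max of all cells' null amplitudes forms
a box, and only amplitudes outside it are flagged responsive
(excitatory above, inhibitory below). The box is global across cells by
default (a per-cell option exists). A min/max box over n cells flags
roughly `2·m/(n+1)` of null-distributed cell–modality pairs (m
modalities), ≈ 2.5 % at 237 cells and three modalities; because the box
edges are order statistics, single-session false-positive fractions
scatter widely around that rate, so the calibration test measures the
rate over replicate sessions.

Multimodal overlap is compared to the independence expectation. The
published marginals are proportions *among responsive cells*;
conditioning on responding to at least one modality makes those
marginals negatively dependent, so the naive product of conditional
marginals overstates the expected trimodal fraction. The implementation
inverts the conditional marginals to unconditional ones by fixed point,
computes exactly-k probabilities under independence, re-conditions on
≥ 1, and checks the top-overlap count with an exact binomial test.

Evoked-movement trials are those with a bout onset within 5 s of the
stimulus (the plausible evoked-latency range); hunger-state contrasts
use paired t-tests at α = 0.0125 (0.05/4, four modalities).

## Photometry

Bulk population fluorescence at 500 Hz. Stimulus-locked latency:
per-event ΔF/F₀ with a 2 s pre-event mean F₀, average across events,
z-score, 5-sample smoothing, then the sustained-crossing rule (1σ above
the 2.5–0 s pre-stimulus baseline, held ≥ 0.2 s). Locomotion-locked:
240 s moving-mean F₀, 50-sample smoothing, baseline 10–6 s before
onset, search from −6 s (population activity may lead movement, so
latency can be negative). Smoothing is applied after trial averaging.
The σ is that of the baseline window, consistent with the
classification convention. Onsets are resolved to one sample (2 ms);
no sub-sample refinement is attempted. When a baseline has numerically
zero variance the threshold degenerates to the baseline level and a
strict deviation is required, so noiseless steps resolve to the first
post-step sample rather than to floating-point jitter.

## Dose-response fits and histology

Two modified Hill forms are first class: increasing
`S = S_max·F^h/(EC50^h + F^h)` and decreasing
`P = P_max − P_max·F^h/(IC50^h + F^h)`. The source text assigns the
increasing form to a figure whose caption calls its fit "inverse
sigmoidal", which looks swapped; rather than guessing intent, the
caller chooses the form and both are tested. Fitting is least squares
with a multi-start grid (h ∈ {0.5, 1, 2, 4} × x50 at the data
quartiles); the best converged start wins and total failure raises with
per-start diagnostics. Noiseless data are inverted to 1e-6; with 2 %
additive noise the median per-parameter error over 100 draws is below
5 % on a 10-point log-spaced dose ladder.

Histology summaries are ratios of section counts: specificity
= 100·double/(double+marker-only), penetrance = 100·double/marker⁺-cells
of the neuropeptide, percent-remaining = 100·counts/reference-counts.
Note the per-section pooled specificity (97.6 % from 242/6) differs
slightly from a per-animal mean (97.4 %); the function computes the
pooled ratio of whatever counts it is given.

Standard paired/unpaired t and rank-sum tests are delegated to scipy;
only thin reporting wrappers live here.

## The synthetic generator

The generator emulates a head-fixed treadmill session:

- **Locomotion** (`gen_locomotion`): trapezoidal bouts (0.5 s ramps)
  with lognormal plateau speed (median 5 cm/s, σ 0.35 log-units,
  floor 1.5 cm/s so every bout clears the 1 cm/s threshold) and
  lognormal plateau duration (median 5 s, σ 0.45), at a configurable
  bout rate (default 1/min), separated by a refractory gap of at least
  20 s. The gap serves two purposes: stationary epochs for decoding
  exist, and the reporter decay tail (τ ≈ 1.8 s) of the preceding bout
  has fully left the 10–6 s pre-onset baseline window — with a 10 s gap
  that tail biases the baseline upward and systematically turns true ON
  cells into apparent down-up cells. The returned bout table is the
  generator's own event log, measured from the rendered samples.
- **Subtype templates** (`default_templates`): ON 1→10 Hz starting 1 s
  before onset; OFF 5→0.3 Hz (the suppressed-cell resting rate is not a
  measured quantity and is exposed as a parameter, default 5 Hz);
  up-down 3→10 Hz for 2 s then 0.3 Hz lasting 4 s beyond bout offset
  (the suppression must outlast the bout: reporter decay from the
  initial transient otherwise masks the dip for median-length bouts);
  down-up 5→0.3 Hz for 2 s then 10 Hz; non-modulated constant 2 Hz.
  All rates sit in the physiological 0–15 Hz instantaneous range.
  Mixture defaults 31/10/33/20/6 % (ON/OFF/up-down/down-up/non-mod).
- **Stimuli** (`gen_stimuli`): blocks containing each modality exactly
  once in random order; inter-stimulus interval 15 s plus a uniform
  0.1–15 s draw, re-randomised per stimulus. The null modality never
  modulates any cell, by construction.
- **Spikes** (`gen_spikes`): inhomogeneous Poisson with the template
  rate around each bout plus 2 s rate steps of `sensory_gain` Hz
  (default 5) after stimuli for responsive cells (responsiveness drawn
  independently per modality, default probability 0.4 — independence is
  exactly what the chance-overlap analysis assumes, so it can be
  tested). Spikes are drawn exactly per constant-rate segment, so rate
  steps are sharp to machine precision — necessary for the 2 ms
  photometry latency checks.
- **Fluorescence** (`spikes_to_fluor`): the reporter kernel is a
  double exponential (rise 0.2 s, decay 1.8 s, typical of GCaMP6s)
  delayed by 0.15 s, the measured lag from spiking onset to detectable
  fluorescence at this resolution; peak fluorescence of constant-rate
  trains is monotone and near-linear in rate over 1–15 Hz (R² ≥ 0.95).
  `F(t) = f_base·exp(−t/bleach_tau)·(1 + Σ kernel) + gain·common(t) +
  noise`; the shared neuropil background `common` is 0.5 Hz low-passed
  Gaussian noise, gain 0.3. Defaults: per-spike increment 3 % of
  `f_base`, white noise 25 % of `f_base` per frame at 10 Hz.
  The noise regime was chosen so that frame-wise measurement noise
  dominates spike shot noise. The classification σ is estimated from a
  4 s window of the bout-averaged trace, which is only an honest noise
  estimate when the noise is uncorrelated between frames; Poisson shot
  noise filtered through a 1.8 s kernel is correlated over seconds and,
  if dominant, biases that σ low enough that the 2σ extremum rule fires
  on noise. Frame-noise-dominated traces are also the realistic case
  for deep-brain GRIN-lens imaging. Under the defaults, per-bout peak
  responses exceed 4σ of the smoothed single-trial noise.
- **Rendering** (`render_stack`): disk ROIs on a grid; ROI pixels carry
  their trace exactly, background pixels the common neuropil signal, so
  extraction has a construction oracle. Overlapping layouts raise.

What the generator does **not** emulate: biophysical calcium dynamics
(buffering, saturation, sublinear summation), dendritic and motion
artefacts, slow drifts in cell health, correlated trial-to-trial
excitability, or behaviour video. Passing tests therefore demonstrate
that the analysis rules recover the structure they assume, at realistic
noise — not that they are robust to every artefact of real recordings.

## Validation scale and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
under it. The test suite validates subtype recovery at 500 cells / ~44
bouts (≥ 95 % label agreement, with monotone degradation over a
25/200/600 noise sweep), decoder chance at 60+ permuted epochs
(|mean − 50 %| < 5 points), and null-box calibration at 237 cells × 6
replicate sessions — sizes chosen to keep the full suite under a couple
of minutes on one CPU while leaving the statistical margins wide.
`scripts/acceptance.py` recomputes the decoder chance level at the full
study scale (6 pseudo-animals × 60 epochs × 40 cells).
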