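# honpipe

Analysis pipeline for ensemble calcium imaging of hypocretin/orexin
neurons (HONs) around locomotion and sensory stimulation — with a
matched synthetic-data generator so the whole analysis is verifiable
end to end without any recordings.

HONs in the lateral hypothalamus modulate their activity on sub-second
timescales around movement. Imaged with GCaMP6s through GRIN lenses,
their bout-averaged activity profiles fall into five classes — ON, OFF,
up-down, down-up and non-modulated — defined by a baseline ± 2σ rule on
the peri-locomotion average. The package implements that classification
and everything around it:

- **`synthgen`** — forward simulation: trapezoidal locomotion bouts,
  randomised stimulus blocks with a response-free null stimulus,
  subtype-specific inhomogeneous-Poisson spiking (0–15 Hz),
  spike-to-fluorescence convolution with a delayed double-exponential
  reporter kernel (report delay 0.15 s, rise 0.2 s, decay 1.8 s),
  photobleaching, shared neuropil background, noise, and optional
  rendering to image stacks with ROI masks — plus full ground truth.
- **`traces`** — ROI extraction with Chebyshev-ring neuropil masks,
  `F_raw − F_np` subtraction, ΔF/F₀ (moving median/mean or pre-event
  baseline), z-scoring (optionally across concatenated sessions),
  boxcar smoothing, and the sustained threshold-crossing onset rule.
- **`locomotion`** — bout detection (speed > 1 cm/s), bout statistics,
  peri-event alignment, baseline-normalised comparisons.
- **`subtypes`** — the five-way classification, per-cell onset times
  (1σ deviation held ≥ 2 s) and active-frame fractions.
- **`correlation`** — per-bout activity correlations with speed,
  distance and duration; population regression; fluorescence–speed
  cross-correlograms.
- **`prediction`** — online movement-prediction variable from
  early-leading ON cells, detection metrics, linear SVM decoding
  (C = 1, 8-fold × 10 repeats) of movement vs stationary epochs with a
  label-permutation chance, and ROC-AUC time courses per subtype.
- **`sensory`** — response amplitudes (mean z, 1–4 s post-stimulus,
  stationary trials only), null-stimulus response box, multimodal
  overlap vs chance, evoked- vs self-paced-movement comparisons,
  hungry/re-fed contrasts (α = 0.0125).
- **`photometry`** — 500 Hz population-signal pipeline and onset
  latencies (2 ms resolution).
- **`statsfits`** — modified Hill dose-response fits
  (`S = S_max·F^h/(EC50^h+F^h)` and the decreasing counterpart) and
  histology count summaries (specificity, penetrance,
  percent-remaining).
- **`pipeline` / `cli`** — end-to-end orchestration and the `honpipe`
  command.

See `docs/methods.md` for the model, parameter defaults and design
choices.

## Worked example

Run the full synthetic analysis — simulate, preprocess, detect bouts,
classify, decode, score sensory responses — from one seed:

```bash
honpipe run --seed 3 --out demo/
```

prints

```json
{
  "n_bouts": 14,
  "subtype_proportions": {
    "up_down": 0.333, "ON": 0.283, "down_up": 0.233,
    "OFF": 0.117, "non_mod": 0.033
  },
  "label_recovery": 0.95
}
```

and writes traces, bout/stimulus tables, the per-cell subtype table, a
ground-truth confusion matrix and a JSON summary into `demo/`. Here the
classifier recovered 95 % of the generator's cell labels from 14 bouts
of a 20-minute session; the recovered subtype proportions track the
generated 33/31/20/10/6 % mixture. The summary also reports decoding:
in this run the linear SVM classified movement vs stationary epochs at
94 % accuracy in the 800 ms before movement onset, against a
permuted-label chance of 42–50 % (13 epochs per class — small-sample
chance scatters around 50 %).

The same stages are exposed individually (`honpipe simulate`, `bouts`,
`classify`, `decode`, `sensory`, `photometry`, `fit-hill`), and the
library functions accept your own CSV/TIFF inputs in the documented
layouts.

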