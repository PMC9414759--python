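# ffhrisk

Pre-impact fall-from-height (FFH) risk prediction from wearable IMU signals.

Construction workers wear a trunk-mounted 6-axis IMU (3-axis acceleration in
g, 3-axis angular velocity in deg/s, 100 Hz). The severity of an impact is
summarised by the peak of the acceleration sum vector magnitude

    A_SVM(t) = sqrt(Acc_x² + Acc_y² + Acc_z²),   G_SVM(t) analogously,

in g. The idea of pre-impact risk prediction: a model that sees only the
window from 0.7 s to 0.2 s *before* the impact peak — 50 samples × 8 channels
(AX, AY, AZ, ASVM, GX, GY, GZ, GSVM) — predicts the peak A_SVM ŷ that is about
to occur. Trials with predicted peaks of **9 g or higher** are classified as
FFH risk, in time to trigger protection (e.g. a wearable airbag).

`ffhrisk` implements this as a fully testable pipeline:

- **`synthetic_data`** — seeded generator for 25 movement types: 15 non-fall
  working movements (NF01–NF15), 5 low-hazard ground falls (LF01–LF05), 5
  high-hazard falls from height (HF01–HF05, with 2–3 m falls performed by an
  instrumented dummy). Peak distributions follow the class structure NF 1–4 g
  (NF15, a 0.7 m jump: 5–9 g), LF mostly 4–9 g with slips LF03/LF04 at
  10–13 g, HF ≥ 9 g; falls include a weightless segment of duration
  √(2h/g).
- **`preprocessing`** — SVM channels, peak location, window extraction,
  stratified 70 % (human) / 60 % (dummy) train–test split.
- **`models`** — four small neural regressors (1D-CNN, 2D-CNN, LSTM,
  Conv-LSTM) trained with MAE or MSE loss, batch size 1, Adam, early stopping
  with best-epoch restoration. Implemented on a compact numpy reverse-mode
  autodiff engine; gradients are verified against finite differences.
- **`tuning`** — exhaustive grid search over layer sizes ({8,16,32,64}² for
  CNNs/LSTM, {16,64}⁴ for Conv-LSTM), selected by validation error.
- **`evaluation`** — MAE (g), MSE (g²), 9 g-threshold confusion counts,
  sensitivity / specificity / accuracy (%), per-movement true-vs-predicted
  summaries.
- **`cli`** — the `ffhrisk` command: `simulate`, `preprocess`, `tune`,
  `train`, `evaluate`, `run`.

## Worked example

Run a small end-to-end experiment (2 synthetic subjects, one trial each,
1D-CNN with MAE loss, two epochs — seconds, not minutes):

```sh
ffhrisk run --config examples/tiny.yaml
```

with `examples/tiny.yaml`:

```yaml
n_subjects: 2
human_trials: 1
dummy_trials: 1
master_seed: 5
architectures: [cnn1d]
losses: [mae]
max_epochs: 2
patience: 2
outdir: tiny_run
```

The log ends with

```
... INFO ffhrisk: extracted 46 windows; split 21 train / 25 test
... INFO ffhrisk: trained cnn1d/mae: stopped epoch 2, best val 8.6560
... INFO ffhrisk: cnn1d/mae: MAE 5.873 g, MSE 73.484 g^2, accuracy 76.0%
```

meaning the held-out predictions (25 test trials) missed the true impact
peaks by 5.9 g on average and 76 % of trials landed on the correct side of
the 9 g risk threshold — crude, as expected from a two-epoch toy run.
`tiny_run/reports/` then contains the full JSON report, the per-movement
true/predicted table, and Table-style CSV summaries; `tiny_run/models/`
holds the checkpoint and training history.

A realistic desk-scale experiment uses 4+ subjects, 3 trials and default
epochs (`max_epochs`/`patience` omitted), and takes a few minutes per
architecture.

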