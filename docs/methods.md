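# Methods

## Problem and model

A trunk-mounted 6-axis IMU samples 3-axis acceleration (g) and angular
velocity (deg/s) at 100 Hz. Impact severity is summarised by the peak of the
acceleration sum vector magnitude A_SVM = √(AX²+AY²+AZ²) over a trial, in g.
The pipeline regresses the pre-impact window — the 50 samples from 0.7 s to
0.2 s before the peak, as an 8-channel matrix (AX, AY, AZ, ASVM, GX, GY, GZ,
GSVM) — onto the peak, and classifies a trial as fall-from-height (FFH) risk
when the predicted peak is 9 g or higher. Ground truth for classification
uses the measured peak against the same threshold (the movement-category
label is reported alongside but is not the truth criterion: a hard ground
slip can exceed 9 g, and that is the quantity that matters for injury).

The regression errors are MAE = (1/N)Σ|ŷᵢ−yᵢ| (g) and MSE = (1/N)Σ(ŷᵢ−yᵢ)²
(g²); classification is summarised by sensitivity, specificity and accuracy
in percent. Rates with empty denominators are reported as undefined rather
than zero. The report writer asserts MAE ≤ √MSE on every prediction set.

## Synthetic data generator

No public recordings exist for this protocol, so the generator is a
first-class, tested component that emulates the study conditions:

- 25 movement types: NF01–NF15 (ordinary work), LF01–LF05 (ground-level
  trips/slips/fainting), HF01–HF05 (falls from 0.7–3 m; the 2 m and 3 m
  falls, HF01/02/04/05, are dummy trials). Defaults: 20 subjects × 3 trials
  per human movement, 5 trials per dummy movement (1260 + 20 recordings).
- Per-movement peaks are truncated normals bounded by the class ranges:
  NF 1.3–4 g, NF15 5–9 g, LF01/02/05 4–9 g, LF03/04 10–13 g, HF 9–16 g.
  Forward falls carry a +2 g mean over vertical falls at equal height
  (feet-first landings transfer less energy to the trunk sensor). Means/sds
  within those bounds are the package's own choices; only the ranges are
  documented study facts. The LF03/04 sd (0.7 g) is kept moderate so draws
  fill the 10–13 g band without heavy truncation; the study describes these
  slips as the most variable movements, which is a known simplification
  here.
- Waveform: gravity projection (≈1 g on one axis) + band-limited Gaussian
  noise (SD 0.05 g, 15 Hz low-pass); movement-specific low-frequency
  oscillation whose amplitude scales with the drawn peak (so the pre-impact
  window carries a severity cue, as real pre-fall dynamics do); for falls a
  weightless segment (|a| ≈ 0.02 g) of duration √(2h/g) ending at impact; a
  30 ms half-sine impact pulse that realises the drawn peak exactly; then
  exponentially decaying ringing. Everything outside the pulse is capped at
  0.9× the drawn peak, so the global maximum is unique and the window
  (which ends 0.2 s earlier) never contains it.
- Gyro channels: low-passed noise plus activity-scaled bursts; rotation
  bursts near impact are large (≈350 deg/s) for forward falls and trips,
  small (≤50 deg/s) for vertical falls. Uncalibrated to any measured value.
- Seeding: the master seed spawns one substream per recording from a CRC of
  (movement, subject, trial), so the set generated is independent of
  insertion order and byte-identical across reruns; CSV output uses a fixed
  float format for reproducible files.

What the generator does **not** emulate: sensor saturation/drift, realistic
noise spectra, multi-peak impacts, inter-subject biomechanical variability
beyond the peak/amplitude scaling, or orientation changes of the gravity
axis during activity. Passing recovery tests therefore demonstrate that the
pipeline recovers structure the generator encodes — not field performance on
real falls.

## Windowing and split

The peak index is the argmax of per-sample A_SVM (earliest index on ties);
the window is the half-open sample range [peak−70, peak−20) at 100 Hz —
exactly 50 samples. Peaks earlier than sample 70 raise an explicit
"insufficient pre-peak history" error naming the recording. One window per
recording. The train/test split is stratified by movement code with 70 % of
human and 60 % of dummy recordings in training, per-stratum train count
floor(frac·n), seeded and reproducible. No amplitude normalisation is
applied by default (the reference protocol feeds raw channels); an optional
per-channel z-scoring (`zscore: true` in the run config) standardises all
windows with statistics computed on the training split only.

## Models and training

Four regressors map the window to one linear output unit (hidden
activations ReLU; identity output since peaks are unbounded):

- **1D-CNN**: two blocks of Conv1D(kernel 2, stride 2, valid) → max-pool 2;
  time axis 50→25→12→6→3; flatten → dropout 0.25 → linear.
- **2D-CNN**: the window as a 50×8×1 image; two blocks of Conv2D(kernel
  (4,4), stride (2,2), same-padding) → max-pool (2,2); 50×8→25×4→12×2→6×1→
  3×1. The second pool meets a width-1 axis; the pooling window is clipped
  to the available extent per axis.
- **LSTM**: two stacked LSTM layers over the raw 50-step sequence (standard
  cell: sigmoid gates, tanh candidate, forget bias 1, Glorot input weights,
  orthogonal recurrent weights).
- **Conv-LSTM**: the 1D-CNN front-end (3 remaining steps) feeding two LSTM
  layers.

Training: batch size 1; Adam with learning rate 1e-3 (β=0.9/0.999,
ε=1e-8); loss MAE or MSE; a seeded 20 % validation slice of the training
windows, stratified by movement category, monitors the loss for early
stopping (CNNs: up to 200 epochs, patience 100; LSTM family: 50/10) with
best-epoch parameter restoration. Dropout 0.25 precedes the output in all
four architectures during training only. Seeded initialisation gives exact
same-device repeatability; bit-exact cross-platform equality is not
promised.

The networks run on a small in-package reverse-mode autodiff engine over
numpy (float64, per-sample graphs — batch size 1 makes vectorised batching
unnecessary). Convolutions reduce to reshapes + matmuls (the kernel-2/
stride-2 geometry makes output steps disjoint; the 2-D kernel is a sum of 16
strided-slice matmuls). Gradients of every operation and of all four full
architectures are tested against central finite differences.

## Grid search

Layer sizes come from fixed candidate sets: {8,16,32,64}² for 1D-CNN,
2D-CNN and LSTM; {16,64}⁴ for Conv-LSTM (16 configurations each). Every
point trains with the same seed — hence the same validation slice — and is
scored by its best validation loss in the training loss's own units;
selection by test error would leak. Ties resolve to the configuration with
fewer trainable parameters, then lexicographically smaller sizes. Individual
training failures are recorded per row and do not abort the scan.

## Numerical and design choices

- Peak exactly at the threshold (9.0 g) classifies as FFH ("9 g or higher").
- Sample standard deviations in per-movement summaries use the n−1
  denominator and are reported as not-available at n=1.
- The sigmoid uses the numerically stable two-branch form; angular
  velocities are clipped to ±2000 deg/s (gyroscope full-scale).
- NF15 (0.7 m jump) is modelled with a genuine free-fall phase; free-fall
  duration checks target the HF movements.
- Problem sizes in the test suite and acceptance script are scaled to desk
  hardware: the recovery experiment uses 4 subjects (272 trials, ~180
  training windows), which keeps every class represented in both splits
  while the full grid search for the CNN and Conv-LSTM remains exhaustive.
  The standalone LSTM is compared at its reference sizes (8, 16) because a
  full LSTM grid is by far the most expensive scan at 50 sequence steps.

## Known limitations

- The generator's severity cue (pre-impact oscillation amplitude scaling
  with the drawn peak) makes within-class peaks learnable by construction;
  real slips and trips are noisier, and held-out errors here should be read
  as recovery of encoded structure, not expected field error.
- Classification difficulty concentrates at the 9 g boundary (NF15 and
  LF01/02/05 end where HF begins); models systematically underestimate the
  rarer high-peak ground slips (LF03/04), the same imbalance-driven
  underestimation the pre-impact prediction literature reports.
- Batch-size-1 training with per-sample dropout is noisy; run-to-run
  variation across seeds of a few percentage points in accuracy is normal
  at this scale.
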