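# Methods

## Problem and model

`ppgbp` estimates systolic and diastolic blood pressure (SBP/DBP, mmHg)
from a single-site photoplethysmogram (PPG).  The estimation pipeline
follows the image-based multimodal cross-attention design:

1. **Preprocessing.**  The raw PPG is band-pass filtered with an order-3
   Butterworth design (0.5–8 Hz) applied as cascaded second-order sections,
   forward–backward by default so the net phase shift is zero and beat
   morphology stays aligned with its labels.  The first and second time
   derivatives (velocity vPPG and acceleration aPPG) are computed on the
   full filtered record by central differences (one-sided at the edges;
   the second derivative is the first-order operator applied twice).
   Derivatives are taken *before* segmentation so overlapping windows agree
   exactly on shared samples.  The record is then cut into 15-s windows
   with 66.67 % overlap (hop 5 s); trailing samples are dropped.
2. **Rendering.**  Each window's PPG, vPPG and aPPG traces are rasterized
   into fixed-size images by a deterministic polyline rasterizer: amplitude
   is min–max normalized per window onto the drawing area (so images are
   invariant to sensor gain and offset), time maps linearly to columns, and
   the trace is drawn as a 2-px line on a plain background, replicated to
   3 channels.  A plotting library would tie the pixels to its version and
   DPI; the rasterizer makes the image a bit-exact function of the samples.
3. **Feature extraction.**  A convolutional backbone maps each image to a
   grid of spatial feature tokens.  Two kinds share one interface: the
   pretrained ResNet-50 trunk (7×7×2048 tokens for 224×224 input; optional
   torch dependency, classifier head removed) and a self-contained `tiny`
   backbone — three stride-2 3×3 conv blocks, 3→8→16→32 channels with ReLU
   — giving 28×28×32 tokens at 224×224 and 12×12×32 at 96×96.  Images
   enter the tiny backbone in an ink-positive encoding (trace = 1,
   background = 0): with the background at zero, activations — and hence
   gradients — are driven by the trace rather than by the page.  Weights
   are He-normal so variance survives the ReLU cascade.
4. **Cross-attention fusion.**  PPG tokens form the queries, vPPG tokens
   the keys, aPPG tokens the values:
   Q_i = X_PPG W_i^Q, K_i = X_vPPG W_i^K, V_i = X_aPPG W_i^V;
   head_i = softmax(Q_i K_i^T / √d_k) V_i; the h heads are concatenated and
   projected by W^O.  Each modality first passes a ReLU adapter from the
   backbone channel count to d_model.  The fused vector is the mean of the
   per-query fused tokens, and a fully connected layer maps it to
   (SBP, DBP).  Attention runs over the spatial token sequence: with one
   pooled vector per modality the softmax has a single key and the block
   degenerates to passing the value modality through (that literal reading
   stays available as `attend_over="vector"`, and `fusion_mode="head_mean"`
   keeps the alternative head-averaging reading).
5. **Training.**  Mean squared error summed over both targets, Adam,
   validation split held out before training, learning-rate halving on
   validation plateau, early stopping, best-validation weights restored.
   Defaults follow the reference protocol (lr 1e-4, batch 16, 200 epochs,
   val split 0.1, k = 5).  Targets are z-scored internally on the training
   portion and predictions de-standardized to mmHg: Adam moves parameters
   by about one learning rate per step, so raw targets with a ~100 mmHg
   offset would spend the whole budget traversing the bias.  `kfold_evaluate`
   wraps training in k-fold cross-validation (subject-grouped on request,
   since overlapping windows leak across window-level splits) and pools the
   out-of-fold predictions; every downstream statistic is computed on that
   pool.

All neural components — convolutions, dense layers, scaled dot-product
attention, Adam — are implemented in NumPy with hand-derived backward
passes, verified against central finite differences in the test suite.

## Evaluation stack

Point metrics: R² = 1 − SSE/SST, RMSE, MAE, ME, and the sample SD (n−1) of
the error (so RMSE² = ME² + (n−1)/n·SD² exactly).  Confidence intervals are
percentile bootstrap over paired resamples (default 1000 iterations,
α = 0.05); a resample on which a statistic is undefined is redrawn with a
capped retry count.  Bland–Altman agreement reports the bias and the
limits of agreement bias ± 1.96·SD of the differences, each with bootstrap
CIs.  AAMI: |ME| ≤ 5 mmHg and SD ≤ 8 mmHg, inclusive.  BHS: percent of
absolute errors within 5/10/15 mmHg (inclusive); a grade requires all three
of its thresholds — A (60, 85, 95), B (50, 75, 90), C (40, 65, 85), else D.
Percent improvement is 100·(improved − baseline)/baseline for
higher-is-better metrics and 100·(baseline − improved)/baseline for
lower-is-better ones.

## Synthetic data generator

No public PPG–BP corpus ships with the package, so the simulator plants a
known, controllable morphology–BP link and every claim the tests make is
about recovering that link.  Each beat of period T = 60/HR is two
Gaussians: a systolic peak at 0.30 T (unit amplitude) and a diastolic
component at 0.65 T.  The link:

* amplitude ratio A_d/A_s = clip(0.8 − ls·0.004·(SBP − 120), 0.1, 0.95),
* systolic width σ_s = 0.10 T·(1 + ls·0.005·(DBP − 80)),

with link strength ls ∈ [0, 1] (1 by default; 0 decouples waveform from
labels).  The diastolic width is fixed at 0.16 T.  SBP ~ U(90, 180) and
DBP ~ U(55, 110) are redrawn until the pulse pressure is ≥ 20 mmHg
(conditioning that raises the mean SBP to 141.1 mmHg — the exact truncated
mean, verified in a test against Monte-Carlo and closed-form oracles).
Heart rate ~ U(55, 95) bpm per record, independent of BP.  Baseline wander
is a 0.25 Hz sinusoid of amplitude 0.3 and measurement noise is white
Gaussian with SD 0.02 (signal units).  Each record carries its
`truth_params` so tests can assert the link without re-estimating
morphology from noisy samples.

What the simulator deliberately does **not** model: dicrotic-notch
sharpness, beat-to-beat HR and amplitude variability, motion artifacts,
sensor saturation, and any physiologically validated hemodynamics.
Passing the recovery study therefore shows that the pipeline can extract a
planted monotone morphology–BP relationship through the image bottleneck —
not that it reaches the published accuracy on real patients.

## Desk-scale recovery study

`ppgbp.study.run_recovery_study` is the package's scaled-down stand-in for
the full-scale experiments (which used GPU-trained ResNet-50 on thousands
of real records): 40 records × 60 s at 125 Hz, link strength 1, 96×96
images, tiny backbone, d_model 64 with 4 heads, batch 16, at most 30
epochs, subject-grouped 5-fold cross-validation, all statistics on the
pooled out-of-fold predictions.  Choices specific to this scale:

* learning rate 3e-3 — a few hundred optimizer steps must cover what the
  reference protocol covers in 200 epochs at 1e-4;
* no early stop inside the 30-epoch budget, and **tail weight averaging**:
  the returned weights are the mean of the last 10 epochs' weights.  With
  a ~30-window validation split, best-epoch selection is essentially
  noise — it routinely restored near-initial weights — whereas the late
  training trajectory is stable and averaging it removes the epoch
  lottery.  (The general `train` contract still restores the
  best-validation checkpoint by default; tail averaging is the
  `tail_average` option.)
* **time-rescaling augmentation** (`augment_time_crop=0.4`): every epoch,
  each training window is re-rendered from a random sub-span of 60–100 %
  of its length.  Beat density (heart rate) is the most salient image
  feature and is spuriously correlated with BP in any ~30-subject sample;
  the planted cues — diastolic/systolic amplitude ratio and systolic width
  *relative to the beat period* — are invariant under time rescaling, so
  the augmentation removes the shortcut without touching the signal;
* **two training restarts per fold** (`ensemble=2`): a restart that failed
  to converge is cleanly separated by its final validation loss (about
  2–3× the converged members') and is dropped; the converged members'
  predictions are averaged;
* **test-time crop averaging** (`tta_crops=4`): each test prediction is
  the mean over the full-window rendering plus four random crop
  renderings.  Training sees crop-rendered windows, so the full-window
  view alone is slightly out of distribution; averaging the views both
  fixes that mismatch and removes prediction noise, and is the single
  largest contributor to pooled accuracy;
* the fold split is subject-grouped, so the reported pooled metrics are
  for subjects never seen in training; the epoch-monitoring validation
  split is window-level as in the reference protocol;
* study models run in float32 (the default is float64, which the
  finite-difference gradient tests use).  Tokens are layer-normalized
  (no affine) before the fusion block; without it, attention training
  shows init-dependent plateaus of 10–20 epochs.

The problem sizes were chosen so the study completes comfortably on one
CPU; they are stated here so its numbers are read as what they are — a
small-sample synthetic recovery, with per-fold variance to match.

## Numerical choices and degenerate inputs

* Softmax uses max-subtraction; attention rows sum to 1 within 1e-5.
* Min–max rendering of a constant trace maps to the vertical center row.
* R² on all-equal references is reported as NaN (undefined marker); the
  bootstrap redraws such resamples.
* `segment` drops trailing samples; a signal shorter than one window
  yields an empty result with a logged warning, not an error.
* Beat detection for arterial-pressure waveforms uses a 0.3 s minimum
  inter-peak distance and 10 mmHg prominence — artifact constants, since
  the source protocol states only max/min per cardiac cycle.
* Window labels from beat-wise data are the arithmetic mean of beats whose
  systolic peak lies inside the window; windows with no complete beat are
  dropped and logged.

## Known limitations

* The `resnet50` backbone kind requires the optional torch/torchvision
  dependency and a pretrained-weight download; everything else, including
  the whole test suite, runs on the NumPy path.
* The fused representation is a permutation-invariant function of token
  *content*; without positional encodings (deliberately out of scope) the
  model recovers amplitude-position information only insofar as training
  shapes the convolution features to encode it.  On the synthetic study
  this is the binding constraint and explains the gap between the model
  and a position-aware linear probe of the same tokens.
* Bootstrap CIs are percentile (not BCa); with n in the hundreds the
  difference is small.
* The AAMI check is the numeric threshold only; the standard's
  subject-count and population-composition requirements are out of scope.
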