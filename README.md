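# ppgbp

Cuffless blood-pressure estimation from a single-site photoplethysmogram
(PPG), for researchers who want a fully inspectable, CPU-only
re-implementation of the image-based multimodal cross-attention approach:
render a PPG window and its first (vPPG) and second (aPPG) derivatives as
images, extract spatial feature tokens with a CNN backbone, fuse the three
modalities with multi-head cross-attention, and regress systolic/diastolic
pressure — then grade the estimates the way BP devices are graded.

## Model

For each 15-s window (band-pass filtered 0.5–8 Hz, rendered per modality):

    Q_i = X_PPG W_i^Q,   K_i = X_vPPG W_i^K,   V_i = X_aPPG W_i^V
    head_i = softmax(Q_i K_i^T / √d_k) V_i
    MHCA(Q, K, V) = Concat(head_1, …, head_h) W^O
    Ŷ_BP = W_BP · X_fusion + b_BP

where X_m are the backbone's spatial tokens for modality m, X_fusion is the
mean of the per-query fused tokens, and Ŷ_BP = (SBP, DBP) in mmHg.
Evaluation reports R², RMSE, MAE, ME, SD with percentile-bootstrap CIs,
Bland–Altman bias ± 1.96·SD limits of agreement, the AAMI verdict
(|ME| ≤ 5 mmHg, SD ≤ 8 mmHg), and the BHS cumulative-error grade
(A = 60/85/95 % of errors within 5/10/15 mmHg; B = 50/75/90; C = 40/65/85).

The neural components (tiny CNN backbone, attention, Adam) are pure NumPy
with hand-derived gradients checked against finite differences; the
pretrained ResNet-50 backbone of the original design is available behind
the optional `ppgbp[resnet]` extra.  No external dataset is required: the
`ppgbp.simulate` module generates synthetic PPG with a documented,
controllable morphology–BP link (see `docs/methods.md`).

## Worked example

```python
from ppgbp.config import SimConfig
from ppgbp.simulate import simulate_record
from ppgbp.preprocess import make_windows
from ppgbp.evaluation import PairedPredictions, regression_metrics, bhs_result

rec = simulate_record(SimConfig(n_records=1, seed=7), 0)
print(f"{rec.record_id}: SBP {rec.sbp_ref:.1f}  DBP {rec.dbp_ref:.1f} mmHg, "
      f"{len(make_windows(rec))} windows")
```

prints

```
rec_0000: SBP 170.7  DBP 97.7 mmHg, 10 windows
```

one simulated minute of PPG at 125 Hz with its reference pressures, cut
into ten 15-s windows (5-s hop).  The full pipeline — simulate, preprocess,
render, k-fold training, evaluation report — runs from the command line:

```bash
ppgbp run --seed 1 --out runs/demo          # writes report.json + manifest
ppgbp info                                   # parameter counts
```

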