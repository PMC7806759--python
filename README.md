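# ecgdelnet

ECG delineation — locating the onset, peak and offset of the P, QRS and T
waves in an electrocardiogram — framed as one-dimensional semantic
segmentation with a fully-convolutional U-Net. The package is aimed at
researchers working with small, per-beat-annotated ECG datasets (e.g.
two-lead ambulatory recordings at 250 Hz) who need a delineator that can be
retrained on new morphologies without hand-tuned signal-processing rules.

## What it does

Per-beat fiducials `w_on <= w_fid <= w_off` for each wave
`W ∈ {P, QRS, T}` are encoded as a three-channel binary mask

```
B[n, w] = 1  if n ∈ [w_on[m], w_off[m]] for some beat m,   else 0
```

and a configurable 1D U-Net (encoder/decoder with skip connections, level-`l`
width `2^l·N`, kernel 3, pooling 2, ReLU activations, sigmoid output) is
trained to predict the mask with a soft Jaccard loss and Adam, under strict
**subject-wise** k-fold cross-validation so that no beat, lead or window of a
test subject ever reaches training. Predicted masks are decoded back to
fiducials and scored with fiducial-membership correspondence matrices,
precision/recall/F1, signed onset/offset errors (true − predicted, ms) and
Dice overlap, plus inter-/intra-observer bias estimators.

The package includes:

- `synthetic` — multi-lead quasi-periodic ECG-like records built from Gaussian
  deflections with *exactly known* fiducials, plus a degraded "low-quality"
  label generator emulating automatic single-lead annotators;
- `ecg_io` — WFDB-dialect signal files (text header + int16 samples), text
  annotation tables and JSON truth sidecars;
- `mask_codec` — fiducials ↔ mask encoding/decoding;
- `augmentation` — six SNR-calibrated ECG noise sources (white noise, random
  spikes, amplifier saturation, 50 Hz powerline, 0.5 Hz baseline wander,
  pacemaker spikes) with hyperparameter jitter;
- `unet1d` — the U-Net family (vanilla / residual / depthwise-separable
  "xception" blocks, spatial dropout, batch norm) on a compact numpy engine
  with hand-written reverse-mode gradients (`ecgdelnet.nn`);
- `training` — subject-wise folds, Jaccard loss, semi-supervised pre-training
  on low-quality labels, experiment-grid driver;
- `evaluation` — detection/delineation scoring and observer-bias estimation;
- `cli` — `ecgdelnet simulate | augment-demo | train | grid | predict |
  evaluate | model-summary`.

## Worked example

```python
import ecgdelnet as e
from ecgdelnet.training import LabelledRecord, TrainConfig

spec = e.SimulationSpec(n_subjects=20, duration=30.0, seed=11)
data = [LabelledRecord(record=r, fiducials=f) for r, f in e.generate_dataset(spec)]
folds = e.make_folds([d.record.record_id for d in data], k=5, seed=1234)
arch = e.ArchitectureConfig(levels=4, blocks_per_level=2, base_width=8, seed=1234)
cfg = TrainConfig(window=512, epochs=15, batch_size=8, learning_rate=5e-3, seed=1234)
runs = e.train(data, folds, arch, cfg)
report = e.evaluate_runs(runs, data, strategy="single_lead", window=512)
print(report.to_frame().to_string(index=False))
```

prints (about six minutes on one CPU):

```
wave   tp  fp  fn  precision  recall       f1  onset_mean_ms  onset_sd_ms  offset_mean_ms  offset_sd_ms     dice  n_matched
   P 1114  27   0   0.976337     1.0 0.988027      -0.043088     3.069209       -0.570916      3.260792 0.972989       1114
 QRS 1186   0   0   1.000000     1.0 1.000000      -0.097808     2.085171        0.266442      1.997428 0.988315       1186
   T 1186   8   0   0.993300     1.0 0.996639       0.087690     4.005780        0.580101      3.678580 0.984496       1186
```

Reading: pooled over all held-out records and leads of the five folds, every
true QRS complex was detected (recall 1.0) with no false detections
(precision 1.0); QRS onsets deviate from the known truth by
−0.10 ± 2.09 ms — about half a sample at 250 Hz — and the QRS mask overlaps
the true mask with Dice 0.99. P and T behave similarly, with a handful of
false positives from fragmented long waves.

The same pipeline runs from the shell:

```sh
ecgdelnet simulate --spec sim.yaml --out data/
ecgdelnet train --data data/ --config train.yaml --out run/
ecgdelnet predict --model run/fold0.npz --record data/sub000.hea --out pred/ --window 512
ecgdelnet evaluate --pred pred/ --truth data/ --out report/
```

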