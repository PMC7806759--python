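# Methods

## Problem setting

ECG delineation assigns to every cardiac cycle the onset, peak and offset of
its P wave (atrial depolarization), QRS complex (ventricular depolarization)
and T wave (ventricular repolarization). The package treats delineation as
binary segmentation: for each wave a per-sample indicator over the closed
interval `[on, off]` (0-based sample indices, both ends inclusive), one
channel per wave. Channels are independent, so cross-channel overlap is
representable; same-channel overlap merges into one run by construction.
Decoding maps each maximal run of ones back to one wave (`on` = first sample,
`off` = last). Because a mask carries no amplitude, the decoded peak is the
extremal |signal| sample inside the run when the signal is available, else the
run midpoint. Runs shorter than `min_duration_ms` (default 20 ms, i.e. 5
samples at 250 Hz) are discarded: this suppresses single-sample speckle
without hiding genuine short waves, and is a configuration knob, not a
post-processing stage — no HMM or morphological smoothing is applied.

## Synthetic data generator

Every beat is a sum of Gaussian deflections: one for P, three
alternating-sign narrow ones (Q, R, S) for the QRS complex, one wider one for
T. A wave's ground-truth onset/offset are the first/last samples where its
own component exceeds 5% of the component's peak magnitude — unambiguous and
resolution-independent — and the peak is the component's extremal sample.
Wave envelopes are laid out sequentially with non-negative PQ and ST gaps, so
the ordering `P.off < QRS.on`, `QRS.off < T.on` holds for every beat by
construction. Records place beats at RR intervals drawn from a configurable
heart rate with fractional Gaussian jitter; each beat's template is perturbed
multiplicatively (default ±10%) and the P wave is deleted with a small
probability (default 5%). Leads are scaled, possibly sign-flipped affine
projections of one source train plus small independent Gaussian noise
(default 0.01 mV), reproducing the inter-lead redundancy that motivates
subject-wise splitting. All draws come from one seeded generator: identical
specifications give identical bytes.

Default study conditions: 20 subjects, 2 leads, 250 Hz, 30 s per record,
60 bpm with 5% RR jitter. Thirty seconds (~30 beats) per subject mirrors the
annotated-beats-per-recording density of expert-labelled ambulatory datasets
while keeping a 5-fold CPU run in minutes; the generator accepts any
duration.

What the generator does *not* emulate: pathological morphology families
(bundle-branch block, flutter waves, biphasic T), non-stationary rhythm,
electrode artefacts, or disagreement between leads about fiducial positions.
Passing tests therefore demonstrate that the pipeline recovers known
ground truth under controlled conditions — not clinical-grade performance on
real recordings.

The low-quality label generator emulates automatic single-lead annotators:
boundaries jittered with Gaussian noise (default SD 8 ms), waves dropped at
random (default 10%), occasional spurious waves inserted in inter-beat gaps
(default 5%), with ordering invariants restored by clipping.

## Data augmentation

Six additive noise sources, each calibrated against the input lead's power
`P_s = mean(x²)` so the noise power is `P_n = P_s / 10^(SNR/10)`:

| source | model |
|---|---|
| AWGN | i.i.d. `N(0, sqrt(P_n))` |
| RS | 5-tap spike template `[0, 0.15, 1.5, −0.25, 0.15]` + per-tap U(−0.25, 0.25), scaled by `sqrt(P_n/f)`, stamped every `1/f` s with random phase |
| AS | clipping residual to `±S_v`, `S_v = p·max|x|` |
| PN / BW | cosine of amplitude `sqrt(2·P_n)` at 50 Hz / 0.5 Hz |
| PS | value `sqrt(P_n/f)` one sample before each QRS onset |

Decisions taken where the noise taxonomy leaves room: the spike rates `f`
are interpreted in events per second (converted through the sampling rate,
consistent with the cosine sources' `f/f_s`); the RS phase is drawn uniformly
so spikes do not correlate with beat positions; the per-tap uniform noise is
redrawn per spike (a test hook disables it); the RS normalization
`sqrt(P_n/f)` is implemented literally, so the realized RS SNR depends on
spike sparsity and is deliberately not forced to match the nominal SNR.
Generation hyperparameters are jittered by `U(±SNR/10)` to maximize input
variability. The composition policy applies each source independently with
probability 0.25, at most three concurrently, with per-application SNR drawn
from 5–30 dB — augmented signals stay recognizable as ECG. Augmentation
never touches labels: all sources are additive or amplitude-limiting, so
fiducial positions are noise-invariant.

## Network

A 1D U-Net: stem convolution (plain convolution at width `N`, so the input's
polarity is not rectified before any feature exists), `L` resolution levels
of `CB` convolutional blocks with level-`l` width `2^l·N`, max-pool 2 between
levels, and a mirrored decoder with nearest-neighbour ×2 upsampling followed
by a convolution halving the width, concatenation of the encoder skip, `CB`
blocks, and a final 1×1 convolution + sigmoid to 3 channels. Kernel size 3,
zero padding everywhere: output length equals input length, which must be
divisible by `2^(L−1)`.

Blocks compose two modules of nonlinearity → regularizers → convolution,
`y = C(R(NL(C(R(NL(x))))))`, with R = spatial dropout then batch
normalization (each individually switchable); the residual and xception
variants add the block input back (through a 1×1 projection when widths
differ), the xception variant using depthwise-separable convolutions.
Applying the nonlinearity to the raw block input is the literal composition;
it differs from conv-first conventions and is kept for comparability across
the three block families. Skip connections concatenate rather than add,
following the original U-Net design. Spatial dropout zeroes whole feature
channels (probability `p`, survivors rescaled by `1/(1−p)`), a stronger
regularizer than unstructured dropout for convolutional features.

The engine underneath (`ecgdelnet.nn`) is a compact numpy implementation with
hand-written reverse-mode gradients for every layer, verified against central
finite differences (note: at exactly-zero pre-activations the ReLU makes the
loss non-differentiable, so gradient checks nudge parameters off zero and use
a small step). Training windows default to 512 samples (~2 s at 250 Hz,
divisible by 2⁶), covering 2–3 beats.

## Training protocol

Subjects are shuffled and partitioned into k = 5 near-equal folds; every
lead, beat and window of a subject stays on one side of the split. The loss
is the smoothed soft Jaccard `1 − mean_c (Σpt + ε)/(Σp + Σt − Σpt + ε)` with
ε = 1 and channel-mean aggregation — the standard differentiable form of the
Jaccard index; it is scale-free per channel, so no class reweighting is
applied. Optimizer: Adam. Defaults — learning rate 5·10⁻³, batch 8, 15
epochs, non-overlapping windows, per-window z-scoring of each input channel —
were chosen for reliable convergence of the small reference model
(L=4, CB=2, N=8) on a single CPU; all are exposed in `TrainConfig`. The
training loop is deterministic end-to-end for a fixed seed (data, folds,
initialization, batch order, dropout and augmentation draws).

Semi-supervised pre-training trains from scratch on the low-quality labels
without augmentation, then fine-tuning continues from those weights on
high-quality labels with the same fold partition for both stages (enforced).
Single-lead training treats each lead as an independent sample and produces
one mask per lead at inference; multi-lead training stacks the leads as input
channels and produces a single mask.

## Evaluation

A true wave `i` and predicted wave `j` correspond when any fiducial (onset,
peak or offset) of one lies inside the closed `[on, off]` interval of the
other — the symmetric membership test over all three fiducials, the most
inclusive reading. Per-lead correspondence matrices are fused with a logical
OR. TP counts matched *true* waves (rows with ≥ 1 match) and FP unmatched
*predicted* waves (columns with none), so one-to-many matches cannot drive a
count negative; precision/recall use the convention 0/0 → 1 (nothing
predicted, nothing false; logged when triggered). Counts are pooled over
records and leads before computing overall precision/recall (micro-averaging).

Boundary errors are computed over TPs only: for each matched true wave, the
signed error (true − predicted, in ms; positive onset error = prediction
early) with the smallest absolute value over matched predictions and leads,
summarized as mean ± SD. When single-lead predictions yield per-lead
matrices of different widths, each lead is scored against its own truth and
pooled. For integer-sample fiducials every error is a multiple of
`1000/fs` ms (4 ms at 250 Hz).

Observer-bias estimators: inter-observer bias matches two annotators' waves
with the same correspondence rule and reports the per-wave mean ± SD of their
boundary differences (a wave type absent from one annotator is skipped).
Intra-observer bias extends each delineated segment by 40 ms on both sides,
computes the normalized cross-correlation (autocorrelation at zero lag = 1)
between all same-type pairs over all overlapping lags, and treats pairs
peaking at ≥ 0.99 as the same morphology; their aligned boundary differences
(best-lag shift removed) enter the per-wave statistics.

## Problem sizes and numerical choices

The cross-validated reference experiment uses 20 subjects × 30 s × 2 leads,
a (4, 2, 8) vanilla U-Net, 512-sample windows and 15 epochs per fold — the
scale at which the full 5-fold pipeline completes in a few minutes on one
CPU while leaving the QRS metrics (recall, onset SD) well inside their
tolerances. The direction-of-effect harness (spatial dropout 0.25 and
low-quality pre-training vs. a plain baseline) uses 8 subjects × 16 s, one
fold, three seeded replicates, and is reported as a logged soft check: at
this scale the sign of the median ΔF1 is noisy — dropping a quarter of 8–16
channels can remove most of a tiny model's capacity — so the harness records
the medians rather than hard-failing on them.

Binarization threshold 0.5 (ties map to 1); mask decoding `min_duration`
20 ms; Jaccard ε = 1; batch-norm momentum 0.1, eps 10⁻⁵; He-normal weight
initialization; Adam (0.9, 0.999, 10⁻⁸). Degenerate inputs: an all-zero lead
has undefined SNR and is rejected by the noise generators; empty fiducial
sets encode to all-zero masks; an empty match set yields an empty error
report (n = 0), not an error; records shorter than the inference window are
zero-padded and cropped back.

## Known limitations

- The synthetic morphology model is deliberately simple; none of the results
  here transfer to claims about real ECG databases.
- The numpy engine targets small models on CPU; there is no GPU path, and
  very deep sweep configurations are built and verified shape-wise rather
  than trained.
- The intra-observer estimator is O(pairs²) per wave type and caps the number
  of compared pairs.
- Multi-lead evaluation assumes the truth shares beats across leads (true
  for the synthetic generator and for multi-lead-annotated datasets);
  lead-specific truths fall back to per-lead scoring.
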