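"""Subject-wise cross-validation training of the 1D U-Net.

The training protocol mirrors common practice for small biosignal datasets:
subjects (not beats or leads) are partitioned into k folds so that no beat of
a test subject — nor any of its leads, which are strongly correlated — can
leak into training.  The loss is a smoothed (soft) Jaccard index averaged
over the three wave channels, optimized with Adam.  An optional
semi-supervised stage pre-trains from scratch on abundant low-quality
(automatically generated) labels without augmentation, after which
fine-tuning continues from those weights on high-quality labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .augmentation import AugmentationPolicy, augment
from .ecg_io import ECGRecord, FiducialSet
from .mask_codec import fiducials_to_mask
from .unet1d import ArchitectureConfig, UNet1d, build_unet, predict_record, _normalize

logger = logging.getLogger("ecgdelnet")

#: smoothing constant of the soft Jaccard loss
JACCARD_EPS = 1.0


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def jaccard_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Soft Jaccard loss ``1 - mean_c (|p.t| + eps) / (|p| + |t| - |p.t| + eps)``.

    ``pred`` holds probabilities in [0, 1] and ``target`` binary labels, both
    shaped (batch, 3, samples).  Bounded in [0, 1]; zero iff ``pred == target``
    on binary inputs.
    """
    return _jaccard(pred, target)[0]


def jaccard_loss_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``pred``."""
    return _jaccard(pred, target)


def _jaccard(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    axes = tuple(i for i in range(pred.ndim) if i != pred.ndim - 2)  # all but channel
    inter = (pred * target).sum(axis=axes)
    union = pred.sum(axis=axes) + target.sum(axis=axes) - inter
    j = (inter + JACCARD_EPS) / (union + JACCARD_EPS)
    n_ch = pred.shape[-2]
    loss = float(1.0 - j.mean())
    # dJ_c/dp_i = (t_i (U+eps) - (A+eps)(1-t_i)) / (U+eps)^2
    denom = (union + JACCARD_EPS) ** 2
    shape = [1] * pred.ndim
    shape[-2] = n_ch
    a = ((inter + JACCARD_EPS) / denom).reshape(shape)
    u = (1.0 / (union + JACCARD_EPS)).reshape(shape)
    grad = -(target * u - (1.0 - target) * a) / n_ch
    return loss, grad


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """Disjoint train/test subject partitions for k-fold cross-validation."""

    k: int
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, test) per fold
    seed: int

    def train_subjects(self, fold: int) -> tuple[str, ...]:
        return self.folds[fold][0]

    def test_subjects(self, fold: int) -> tuple[str, ...]:
        return self.folds[fold][1]


def make_folds(subject_ids: list[str], k: int = 5, seed: int = 1234) -> FoldSplit:
    """Random near-equal subject-wise partition; deterministic per seed."""
    subjects = list(subject_ids)
    if len(set(subjects)) != len(subjects):
        raise ValueError("subject ids must be unique")
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    test_sets = [tuple(order[i::k]) for i in range(k)]
    folds = tuple(
        (tuple(s for s in order if s not in set(test)), test) for test in test_sets)
    return FoldSplit(k=k, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Configuration and data plumbing
# ---------------------------------------------------------------------------

@dataclass
class LabelledRecord:
    """A record with its high-quality truth and optional low-quality labels."""

    record: ECGRecord
    fiducials: FiducialSet
    low_quality: FiducialSet | None = None


@dataclass(frozen=True)
class TrainConfig:
    strategy: str = "single_lead"  # or "multi_lead"
    label_quality: str = "high"  # or "low" (semi-supervised pre-training stage)
    augmentation: AugmentationPolicy | None = None
    learning_rate: float = 5e-3
    epochs: int = 15
    batch_size: int = 8
    window: int = 512
    window_stride: int | None = None  # default: non-overlapping windows
    seed: int = 1234

    def __post_init__(self):
        if self.strategy not in ("single_lead", "multi_lead"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.label_quality not in ("high", "low"):
            raise ValueError("label_quality must be 'high' or 'low'")
        if self.label_quality == "low" and self.augmentation is not None:
            raise ValueError("no augmentation during semi-supervised pre-training")


def _windows_for_subject(item: LabelledRecord, cfg: TrainConfig
                         ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """(x, target, qrs_onsets_in_window) training samples for one subject.

    ``single_lead``: each lead is an independent sample stream; ``multi_lead``:
    leads are stacked as input channels with one (lead-0) target mask.
    """
    fids = item.low_quality if cfg.label_quality == "low" else item.fiducials
    if fids is None:
        raise ValueError(f"record {item.record.record_id} lacks "
                         f"{cfg.label_quality}-quality labels")
    rec = item.record
    W = cfg.window
    stride = cfg.window_stride or W
    out = []
    lead_ids = range(rec.n_leads) if cfg.strategy == "single_lead" else [0]
    for lead in lead_ids:
        n_lead = min(lead, len(fids.leads) - 1)
        mask = fiducials_to_mask(fids.leads[n_lead], rec.n_samples, rec.fs).values.T
        qrs_on = np.array([b["QRS"].on for b in fids.leads[n_lead] if "QRS" in b])
        if cfg.strategy == "single_lead":
            x_full = rec.signal[:, [lead]].T
        else:
            x_full = rec.signal.T
        T = rec.n_samples
        starts = list(range(0, T - W + 1, stride)) if T >= W else []
        for s in starts:
            onsets = qrs_on[(qrs_on >= s) & (qrs_on < s + W)] - s
            out.append((x_full[:, s:s + W], mask[:, s:s + W], onsets))
    return out


@dataclass
class FoldRun:
    fold: int
    model: UNet1d
    history: list[float]
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def train_fold(model: UNet1d, samples: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
               cfg: TrainConfig, fs: float, rng: np.random.Generator) -> list[float]:
    """Optimize one model on pre-extracted windows; returns per-epoch loss."""
    if not samples:
        raise ValueError("empty training fold")
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history = []
    n = len(samples)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xs, ts = [], []
            for i in idx:
                x, t, onsets = samples[i]
                if cfg.augmentation is not None:
                    x = np.stack([
                        augment(ch, fs, cfg.augmentation, rng,
                                qrs_onsets=onsets.tolist(), draw_snr=True)
                        for ch in x])
                xs.append(_normalize(x))
                ts.append(t)
            xb = np.stack(xs)
            tb = np.stack(ts)
            pred = model.forward(xb, training=True)
            loss, grad = jaccard_loss_grad(pred, tb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
        logger.debug("epoch %d loss %.4f", epoch, history[-1])
    return history


def train(dataset: list[LabelledRecord], folds: FoldSplit,
          arch: ArchitectureConfig, cfg: TrainConfig,
          initial_state: dict | None = None) -> list[FoldRun]:
    """Train one model per fold on its training subjects only."""
    by_id = {item.record.record_id: item for item in dataset}
    if cfg.strategy == "multi_lead":
        n_leads = dataset[0].record.n_leads
        if arch.in_channels != n_leads:
            arch = replace(arch, in_channels=n_leads)
    runs = []
    for fold in range(folds.k):
        train_ids = folds.train_subjects(fold)
        samples = []
        for sid in train_ids:
            samples.extend(_windows_for_subject(by_id[sid], cfg))
        model = build_unet(replace(arch, seed=arch.seed + fold))
        if initial_state is not None:
            model.load_state_dict(initial_state[fold] if isinstance(initial_state, dict)
                                  and fold in initial_state else initial_state)
        rng = np.random.default_rng(cfg.seed + 1000 * fold)
        fs = dataset[0].record.fs
        history = train_fold(model, samples, cfg, fs, rng)
        runs.append(FoldRun(fold=fold, model=model, history=history,
                            train_subjects=train_ids,
                            test_subjects=folds.test_subjects(fold)))
        logger.info("fold %d: final loss %.4f", fold, history[-1])
    return runs


def pretrain_then_finetune(dataset: list[LabelledRecord], folds: FoldSplit,
                           arch: ArchitectureConfig, pre_cfg: TrainConfig,
                           fine_cfg: TrainConfig) -> tuple[list[FoldRun], list[FoldRun]]:
    """Two-stage semi-supervised protocol with identical fold assignments.

    Stage 1 trains from scratch on low-quality labels (augmentation is
    disallowed there by ``TrainConfig``); stage 2 continues from the stage-1
    weights on high-quality labels.
    """
    if pre_cfg.label_quality != "low":
        raise ValueError("pre-training stage must use low-quality labels")
    if fine_cfg.label_quality != "high":
        raise ValueError("fine-tuning stage must use high-quality labels")
    pre_runs = train(dataset, folds, arch, pre_cfg)
    fine_runs = train(dataset, folds, arch, fine_cfg,
                      initial_state={r.fold: r.model.state_dict() for r in pre_runs})
    return pre_runs, fine_runs


# ---------------------------------------------------------------------------
# Experiment grid
# ---------------------------------------------------------------------------

def run_experiment_grid(grid: list[dict], dataset: list[LabelledRecord],
                        folds: FoldSplit, base_arch: ArchitectureConfig,
                        base_cfg: TrainConfig, window: int = 512,
                        min_duration_ms: float = 20.0) -> pd.DataFrame:
    """Run each grid point (overrides of architecture/training fields) over all
    folds and tabulate held-out detection/delineation metrics per wave."""
    from .evaluation import evaluate_runs  # deferred: evaluation imports nothing from here

    rows = []
    for gi, overrides in enumerate(grid):
        arch_over = {k: v for k, v in overrides.items()
                     if k in ArchitectureConfig.__dataclass_fields__}
        cfg_over = {k: v for k, v in overrides.items()
                    if k in TrainConfig.__dataclass_fields__}
        pretrain = bool(overrides.get("pretrain", False))
        arch = replace(base_arch, **arch_over)
        cfg = replace(base_cfg, **cfg_over)
        if pretrain:
            pre_cfg = replace(cfg, label_quality="low", augmentation=None)
            _, runs = pretrain_then_finetune(dataset, folds, arch, pre_cfg, cfg)
        else:
            runs = train(dataset, folds, arch, cfg)
        for run in runs:
            report = evaluate_runs([run], dataset, strategy=cfg.strategy,
                                   window=window, min_duration_ms=min_duration_ms)
            for wave, m in report.detection.items():
                rows.append({
                    "config": gi, **{k: str(v) for k, v in overrides.items()},
                    "fold": run.fold, "wave": wave,
                    "precision": m.precision, "recall": m.recall, "f1": m.f1,
                    "onset_mean_ms": report.errors[wave].onset_mean_ms,
                    "onset_sd_ms": report.errors[wave].onset_sd_ms,
                    "offset_mean_ms": report.errors[wave].offset_mean_ms,
                    "offset_sd_ms": report.errors[wave].offset_sd_ms,
                })
    return pd.DataFrame(rows)
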