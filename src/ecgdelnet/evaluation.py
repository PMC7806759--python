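"""Detection and delineation scoring of predicted against true fiducials.

A true and a predicted wave match when any fiducial (onset, peak or offset) of
one lies inside the closed ``[on, off]`` interval of the other; the binary
correspondence matrix H of these matches is fused across leads with a logical
OR.  Detection is scored by precision/recall/F1 over matched waves; boundary
accuracy by the signed true-minus-predicted onset/offset differences (ms) of
the matched pairs, taking, for each true wave, the candidate with the smallest
absolute error over matched predictions and leads.  Observer-bias estimators
quantify the disagreement between two annotators, and — through cross-
correlation matching of morphologically near-identical waves — of one
annotator with themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import correlate

from .ecg_io import ECGRecord, FiducialSet, WAVES, WaveFiducials
from .mask_codec import SegmentationMask, binarize, fiducials_to_mask, mask_to_fiducials, wave_lists

logger = logging.getLogger("ecgdelnet")

#: segment extension for intra-observer cross-correlation matching (ms)
XCORR_WINDOW_MS = 40.0
#: normalized cross-correlation threshold for "same morphology"
XCORR_THRESHOLD = 0.99


# ---------------------------------------------------------------------------
# Correspondence and counts
# ---------------------------------------------------------------------------

def _check_ordered(waves: list[WaveFiducials], name: str) -> None:
    for a, b in zip(waves[:-1], waves[1:]):
        if b.on < a.on:
            raise ValueError(f"{name} wave list not ordered by onset")


def correspondence_matrix(true_waves: list[WaveFiducials],
                          pred_waves: list[WaveFiducials]) -> np.ndarray:
    """Binary M x M-hat matrix: entry (i, j) is 1 iff any predicted fiducial of
    wave j lies in ``[on_i, off_i]`` or any true fiducial of wave i lies in
    ``[on_j, off_j]`` (closed intervals)."""
    _check_ordered(true_waves, "true")
    _check_ordered(pred_waves, "predicted")
    H = np.zeros((len(true_waves), len(pred_waves)), dtype=np.int8)
    for i, tw in enumerate(true_waves):
        for j, pw in enumerate(pred_waves):
            pred_in_true = any(tw.on <= v <= tw.off for v in (pw.on, pw.peak, pw.off))
            true_in_pred = any(pw.on <= v <= pw.off for v in (tw.on, tw.peak, tw.off))
            if pred_in_true or true_in_pred:
                H[i, j] = 1
    return H


def fuse_leads(matrices: list[np.ndarray]) -> np.ndarray:
    """Elementwise logical OR across per-lead correspondence matrices."""
    if not matrices:
        raise ValueError("no matrices to fuse")
    shape = matrices[0].shape
    for H in matrices[1:]:
        if H.shape != shape:
            raise ValueError(f"correspondence shape mismatch: {H.shape} vs {shape}")
    fused = matrices[0].astype(bool)
    for H in matrices[1:]:
        fused |= H.astype(bool)
    return fused.astype(np.int8)


@dataclass
class DetectionMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 1.0  # nothing predicted, nothing false
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 1.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    def __iadd__(self, other: "DetectionMetrics") -> "DetectionMetrics":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def detection_counts(H: np.ndarray, M: int | None = None,
                     M_hat: int | None = None) -> DetectionMetrics:
    """TP/FP/FN from a (fused) correspondence matrix.

    TP counts matched true waves (rows with at least one 1), FP unmatched
    predicted waves (columns with none), FN unmatched true waves — so a
    one-to-many match can never drive a count negative.
    """
    M = H.shape[0] if M is None else M
    M_hat = H.shape[1] if M_hat is None else M_hat
    matched_rows = int((H.sum(axis=1) > 0).sum()) if H.size else 0
    matched_cols = int((H.sum(axis=0) > 0).sum()) if H.size else 0
    tp = matched_rows
    fp = M_hat - matched_cols
    fn = M - matched_rows
    if fp < 0 or fn < 0:
        raise RuntimeError("negative detection count: invariant breach")
    if M_hat == 0 and M > 0:
        logger.debug("empty prediction against %d true waves: precision 0/0 -> 1", M)
    return DetectionMetrics(tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Delineation errors
# ---------------------------------------------------------------------------

@dataclass
class WaveErrors:
    """Signed true-minus-predicted boundary errors (ms) over matched waves."""

    onset_ms: list[float] = field(default_factory=list)
    offset_ms: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.onset_ms)

    @property
    def onset_mean_ms(self) -> float:
        return float(np.mean(self.onset_ms)) if self.onset_ms else float("nan")

    @property
    def onset_sd_ms(self) -> float:
        return float(np.std(self.onset_ms)) if self.onset_ms else float("nan")

    @property
    def offset_mean_ms(self) -> float:
        return float(np.mean(self.offset_ms)) if self.offset_ms else float("nan")

    @property
    def offset_sd_ms(self) -> float:
        return float(np.std(self.offset_ms)) if self.offset_ms else float("nan")

    def extend(self, other: "WaveErrors") -> None:
        self.onset_ms.extend(other.onset_ms)
        self.offset_ms.extend(other.offset_ms)


def delineation_errors(per_lead: list[tuple[list[WaveFiducials], list[WaveFiducials], np.ndarray]],
                       fs: float) -> WaveErrors:
    """Boundary errors over matched true waves, minimized across leads.

    ``per_lead`` holds (true_waves, pred_waves, H) triples whose true lists
    align row-wise (the usual case: multi-lead truth shares beats).  For each
    matched true wave the signed error with minimal absolute value over all
    matched predictions of all leads is kept, separately for onset and offset.
    Positive onset error means the prediction is early (true - predicted).
    """
    ms = 1000.0 / fs
    n_rows = {H.shape[0] for _, _, H in per_lead}
    if len(n_rows) != 1:
        raise ValueError("true wave lists must align across leads")
    errors = WaveErrors()
    for i in range(n_rows.pop()):
        on_cands: list[float] = []
        off_cands: list[float] = []
        for true_waves, pred_waves, H in per_lead:
            tw = true_waves[i]
            for j in np.flatnonzero(H[i]):
                pw = pred_waves[j]
                on_cands.append((tw.on - pw.on) * ms)
                off_cands.append((tw.off - pw.off) * ms)
        if on_cands:
            errors.onset_ms.append(min(on_cands, key=abs))
            errors.offset_ms.append(min(off_cands, key=abs))
    return errors


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def dice_score(mask_a: SegmentationMask, mask_b: SegmentationMask) -> np.ndarray:
    """Per-channel Dice overlap ``2|A.B| / (|A| + |B|)``; 1 when both empty."""
    a, b = mask_a.values, mask_b.values
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (mask_a.is_binary() and mask_b.is_binary()):
        raise ValueError("dice_score expects binary masks")
    inter = (a * b).sum(axis=0)
    total = a.sum(axis=0) + b.sum(axis=0)
    out = np.ones(3)
    nz = total > 0
    out[nz] = 2.0 * inter[nz] / total[nz]
    return out


# ---------------------------------------------------------------------------
# Observer bias
# ---------------------------------------------------------------------------

@dataclass
class BiasReport:
    """Per-wave boundary disagreement (ms) between two annotation sources."""

    errors: dict[str, WaveErrors] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for wave, e in self.errors.items():
            rows.append({"wave": wave, "n": e.n,
                         "onset_mean_ms": e.onset_mean_ms, "onset_sd_ms": e.onset_sd_ms,
                         "offset_mean_ms": e.offset_mean_ms, "offset_sd_ms": e.offset_sd_ms})
        return pd.DataFrame(rows)


def interobserver_bias(o1: FiducialSet, o2: FiducialSet, fs: float) -> BiasReport:
    """Boundary differences (O1 - O2, ms) over waves matched by the
    correspondence rule; a wave type one observer never annotated is skipped."""
    report = BiasReport()
    for wave in WAVES:
        if o1.n_waves(wave) == 0 or o2.n_waves(wave) == 0:
            continue
        pooled = WaveErrors()
        for lead in range(min(o1.n_leads(), o2.n_leads())):
            w1 = o1.wave_list(lead, wave)
            w2 = o2.wave_list(lead, wave)
            if not w1 or not w2:
                continue
            H = correspondence_matrix(w1, w2)
            pooled.extend(delineation_errors([(w1, w2, H)], fs))
        if pooled.n:
            report.errors[wave] = pooled
    return report


def intraobserver_bias(fiducials: FiducialSet, record: ECGRecord,
                       max_pairs_per_wave: int = 2000) -> BiasReport:
    """One annotator's consistency across morphologically near-identical waves.

    Every delineated wave segment, extended by 40 ms on both sides, is
    compared with every other same-type segment via normalized cross-
    correlation over all overlapping lags (normalized so an autocorrelation at
    zero displacement equals 1).  Pairs peaking at or above 0.99 are treated
    as the same morphology; the aligned onset and offset differences — after
    removing the best-lag shift — enter the per-wave mean and SD.
    """
    w40 = int(round(XCORR_WINDOW_MS * record.fs / 1000.0))
    report = BiasReport()
    for wave in WAVES:
        errors = WaveErrors()
        n_pairs = 0
        for lead in range(fiducials.n_leads()):
            waves = fiducials.wave_list(lead, wave)
            segs = []
            for wf in waves:
                start = max(0, wf.on - w40)
                stop = min(record.n_samples, wf.off + 1 + w40)
                seg = record.signal[start:stop, lead]
                if seg.size < 2:
                    logger.info("skipping %s wave at %d: segment too short", wave, wf.on)
                    continue
                segs.append((wf, start, seg))
            for a in range(len(segs)):
                for b in range(a + 1, len(segs)):
                    if n_pairs >= max_pairs_per_wave:
                        break
                    n_pairs += 1
                    wf_a, s_a, seg_a = segs[a]
                    wf_b, s_b, seg_b = segs[b]
                    rho, lag = _best_xcorr(seg_a, seg_b)
                    if rho < XCORR_THRESHOLD:
                        continue
                    ms = 1000.0 / record.fs
                    on_diff = ((wf_a.on - s_a) - ((wf_b.on - s_b) + lag)) * ms
                    off_diff = ((wf_a.off - s_a) - ((wf_b.off - s_b) + lag)) * ms
                    errors.onset_ms.append(on_diff)
                    errors.offset_ms.append(off_diff)
        if errors.n:
            report.errors[wave] = errors
    return report


def _best_xcorr(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Peak normalized cross-correlation and the lag of ``b`` relative to ``a``."""
    norm = np.sqrt(float(np.dot(a, a)) * float(np.dot(b, b)))
    if norm == 0.0:
        return 0.0, 0
    c = correlate(a, b, mode="full") / norm
    k = int(np.argmax(c))
    return float(c[k]), k - (len(b) - 1)


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class DelineationReport:
    """Pooled detection, boundary-error and Dice summaries per wave."""

    detection: dict[str, DetectionMetrics] = field(
        default_factory=lambda: {w: DetectionMetrics() for w in WAVES})
    errors: dict[str, WaveErrors] = field(
        default_factory=lambda: {w: WaveErrors() for w in WAVES})
    dice_inter: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dice_total: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def dice(self) -> dict[str, float]:
        out = {}
        for c, wave in enumerate(WAVES):
            out[wave] = (2.0 * self.dice_inter[c] / self.dice_total[c]
                         if self.dice_total[c] > 0 else 1.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        dice = self.dice()
        rows = []
        for wave in WAVES:
            d = self.detection[wave]
            e = self.errors[wave]
            rows.append({
                "wave": wave, "tp": d.tp, "fp": d.fp, "fn": d.fn,
                "precision": d.precision, "recall": d.recall, "f1": d.f1,
                "onset_mean_ms": e.onset_mean_ms, "onset_sd_ms": e.onset_sd_ms,
                "offset_mean_ms": e.offset_mean_ms, "offset_sd_ms": e.offset_sd_ms,
                "dice": dice[wave], "n_matched": e.n,
            })
        return pd.DataFrame(rows)


def evaluate(pred_fiducials: list[list[dict]], truth: FiducialSet, record: ECGRecord,
             pred_masks: list[SegmentationMask] | None = None,
             report: DelineationReport | None = None) -> DelineationReport:
    """Score one record's predictions against its truth, accumulating into
    ``report`` when given (micro-averaged pooling over records and leads).

    ``pred_fiducials`` holds one decoded beat list per predicted mask: one per
    lead for single-lead inference, or a single list for multi-lead inference
    (then compared against every lead's truth and fused across leads).
    """
    if report is None:
        report = DelineationReport()
    n_leads = truth.n_leads()
    multi = len(pred_fiducials) == 1 and n_leads > 1
    for wave in WAVES:
        if multi:
            pred_w = wave_lists(pred_fiducials[0])[wave]
            per_lead = []
            for lead in range(n_leads):
                true_w = truth.wave_list(lead, wave)
                per_lead.append((true_w, pred_w, correspondence_matrix(true_w, pred_w)))
            if len({len(t) for t, _, _ in per_lead}) == 1:
                fused = fuse_leads([H for _, _, H in per_lead])
                report.detection[wave] += detection_counts(fused, M=fused.shape[0],
                                                           M_hat=len(pred_w))
                report.errors[wave].extend(delineation_errors(per_lead, record.fs))
            else:  # truth beat counts differ across leads: score each lead
                for true_w, pw, H in per_lead:
                    report.detection[wave] += detection_counts(H)
                    report.errors[wave].extend(delineation_errors([(true_w, pw, H)], record.fs))
        else:
            for lead in range(n_leads):
                true_w = truth.wave_list(lead, wave)
                pred_w = wave_lists(pred_fiducials[lead])[wave]
                H = correspondence_matrix(true_w, pred_w)
                report.detection[wave] += detection_counts(H)
                report.errors[wave].extend(delineation_errors([(true_w, pred_w, H)], record.fs))
    if pred_masks is not None:
        for lead, mask in enumerate(pred_masks):
            truth_mask = fiducials_to_mask(truth.leads[min(lead, n_leads - 1)],
                                           record.n_samples, record.fs)
            report.dice_inter += (mask.values * truth_mask.values).sum(axis=0)
            report.dice_total += mask.values.sum(axis=0) + truth_mask.values.sum(axis=0)
    return report


def evaluate_runs(runs, dataset, strategy: str = "single_lead", window: int = 512,
                  overlap: float = 0.5, threshold: float = 0.5,
                  min_duration_ms: float = 20.0) -> DelineationReport:
    """Predict every fold's held-out subjects and pool the scores.

    ``runs`` are trained fold runs (model + test subject ids); ``dataset`` is
    the list of labelled records the folds were drawn from.
    """
    from .unet1d import predict_record  # local import to keep module deps one-way

    by_id = {item.record.record_id: item for item in dataset}
    report = DelineationReport()
    for run in runs:
        for sid in run.test_subjects:
            item = by_id[sid]
            prob_masks = predict_record(run.model, item.record, strategy=strategy,
                                        window=window, overlap=overlap)
            bin_masks = [binarize(m, threshold) for m in prob_masks]
            decoded = []
            for lead, m in enumerate(bin_masks):
                sig_lead = 0 if strategy == "multi_lead" else lead
                decoded.append(mask_to_fiducials(
                    m, signal=item.record.signal[:, sig_lead],
                    min_duration_ms=min_duration_ms))
            evaluate(decoded, item.fiducials, item.record,
                     pred_masks=bin_masks, report=report)
    return report
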