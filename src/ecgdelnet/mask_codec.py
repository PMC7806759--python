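"""Fiducial <-> binary segmentation mask codec.

A delineation label for one lead is a ``samples x 3`` mask (channels ordered
P, QRS, T) in which channel ``w`` is 1 exactly on the union of the closed
intervals ``[on, off]`` of that wave's annotated beats.  Decoding maps each
maximal run of ones back to one wave, dropping runs shorter than a minimum
duration; the three channels are independent, so cross-channel overlap is
allowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import WAVES, Beat, WaveFiducials

#: default minimum decoded wave duration (ms); suppresses single-sample speckle
DEFAULT_MIN_DURATION_MS = 20.0


@dataclass
class SegmentationMask:
    """Per-sample wave occupancy, binary or probabilistic, channels (P, QRS, T)."""

    values: np.ndarray  # samples x 3
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"mask must be samples x 3, got {self.values.shape}")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())


def fiducials_to_mask(beats: list[Beat], n_samples: int, fs: float) -> SegmentationMask:
    """Encode one lead's beats as a 3-channel binary mask (closed intervals)."""
    values = np.zeros((n_samples, 3))
    for beat in beats:
        for c, wave in enumerate(WAVES):
            if wave not in beat:
                continue
            wf = beat[wave]
            if wf.off >= n_samples or wf.on < 0:
                raise ValueError(
                    f"{wave} wave [{wf.on}, {wf.off}] outside record of length {n_samples}")
            values[wf.on:wf.off + 1, c] = 1.0
    return SegmentationMask(values=values, fs=fs)


def binarize(mask: SegmentationMask, threshold: float = 0.5) -> SegmentationMask:
    """Threshold a probabilistic mask; values >= threshold map to 1."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return SegmentationMask(values=(mask.values >= threshold).astype(np.float64), fs=mask.fs)


def mask_to_fiducials(mask: SegmentationMask, signal: np.ndarray | None = None,
                      min_duration_ms: float = DEFAULT_MIN_DURATION_MS) -> list[Beat]:
    """Decode a binary mask to per-wave fiducial lists.

    Each maximal run of ones becomes one wave: ``on`` the run's first sample,
    ``off`` its last.  The peak is the sample of maximum absolute signal inside
    the run when ``signal`` is given, else the run midpoint — masks carry no
    amplitude information.  Runs shorter than ``min_duration_ms`` are dropped.

    Returns one beat dict per wave occurrence (one wave each); detection and
    delineation scoring operate on per-wave lists, so no beat grouping is
    attempted here.
    """
    if not mask.is_binary():
        raise ValueError("mask must be binarized before decoding")
    min_len = max(1, int(round(min_duration_ms * mask.fs / 1000.0)))
    beats: list[Beat] = []
    for c, wave in enumerate(WAVES):
        for on, off in _runs_of_ones(mask.values[:, c]):
            if off - on + 1 < min_len:
                continue
            if signal is not None:
                peak = on + int(np.argmax(np.abs(signal[on:off + 1])))
            else:
                peak = (on + off) // 2
            beats.append({wave: WaveFiducials(on, peak, off)})
    return beats


def wave_lists(beats: list[Beat]) -> dict[str, list[WaveFiducials]]:
    """Per-wave fiducial lists ordered by onset."""
    out: dict[str, list[WaveFiducials]] = {w: [] for w in WAVES}
    for beat in beats:
        for w, wf in beat.items():
            out[w].append(wf)
    for w in WAVES:
        out[w].sort(key=lambda f: f.on)
    return out


def _runs_of_ones(channel: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of ones as closed (first, last) sample pairs."""
    padded = np.concatenate([[0.0], channel, [0.0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))
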