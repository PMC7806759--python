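"""SNR-calibrated ECG noise sources and the training-time augmentation policy.

Six additive noise models tailored to ambulatory ECG: additive white Gaussian
noise (AWGN), random periodic spikes (RS), amplifier saturation (AS), powerline
noise (PN, 50 Hz), baseline wander (BW, 0.5 Hz) and pacemaker spikes (PS).
Each is calibrated against the input lead's power ``P_s = mean(x^2)`` so the
noise power is ``P_n = P_s / 10^(SNR/10)`` for a requested SNR in dB.

All generators return an additive noise sequence of the same length as the
input; the augmented lead is ``x + noise``.  Labels (fiducials/masks) are
noise-invariant and never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NOISE_KINDS = ("AWGN", "RS", "AS", "PN", "BW", "PS")

#: pacemaker-like spike template stamped by the random-spikes source
SPIKE_TEMPLATE = np.array([0.0, 0.15, 1.5, -0.25, 0.15])

#: default per-source SNR range (dB) for training-time draws
DEFAULT_SNR_RANGE = (5.0, 30.0)


def noise_power(x: np.ndarray, snr_db: float) -> float:
    """Target noise power ``P_n = P_s / 10^(SNR/10)`` for signal ``x``."""
    p_s = float(np.mean(np.square(x)))
    if p_s == 0.0:
        raise ValueError("signal power is zero; SNR-calibrated noise is undefined")
    return p_s / 10.0 ** (snr_db / 10.0)


def awgn(x: np.ndarray, snr_db: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """White Gaussian noise with variance ``P_n``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.normal(0.0, np.sqrt(noise_power(x, snr_db)), size=len(x))


def random_spikes(x: np.ndarray, snr_db: float, f: float, fs: float,
                  seed: int | np.random.Generator = 0,
                  tap_noise: bool = True) -> np.ndarray:
    """Periodic spike bursts at rate ``f`` events/second with random phase.

    Each spike is the 5-tap template ``[0, 0.15, 1.5, -0.25, 0.15]`` plus
    (optionally) fresh uniform U(-0.25, 0.25) noise per tap per spike, scaled
    by ``sqrt(P_n / f)``.  ``tap_noise=False`` disables the uniform draw for
    deterministic checks.
    """
    if not 0.0 < f < fs / 2.0:
        raise ValueError(f"spike rate must satisfy 0 < f < fs/2, got f={f}, fs={fs}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    amp = np.sqrt(noise_power(x, snr_db) / f)
    period = fs / f  # samples between spikes
    noise = np.zeros(len(x))
    phase = rng.uniform(0.0, period)
    k = 0
    while True:
        start = int(round(phase + k * period))
        if start >= len(x):
            break
        taps = SPIKE_TEMPLATE.copy()
        if tap_noise:
            taps = taps + rng.uniform(-0.25, 0.25, size=len(taps))
        stop = min(start + len(taps), len(x))
        noise[start:stop] += amp * taps[:stop - start]
        k += 1
    return noise


def amplifier_saturation(x: np.ndarray, p: float) -> np.ndarray:
    """Clipping residual: ``x + AS`` equals ``x`` clipped to ``[-S_v, S_v]``
    with saturation value ``S_v = p * max|x|``."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"saturation proportion must be in (0, 1], got {p}")
    s_v = p * float(np.max(np.abs(x)))
    noise = np.zeros(len(x))
    hi = x >= s_v
    lo = x <= -s_v
    noise[hi] = -x[hi] + s_v
    noise[lo] = -x[lo] - s_v
    return noise


def sinusoid_noise(x: np.ndarray, snr_db: float, f: float, fs: float) -> np.ndarray:
    """Deterministic cosine of amplitude ``sqrt(2 P_n)``: powerline noise at
    f=50 Hz, baseline wander at f=0.5 Hz."""
    if not 0.0 < f < fs / 2.0:
        raise ValueError(f"frequency must satisfy 0 < f < fs/2, got f={f}, fs={fs}")
    amp = np.sqrt(2.0 * noise_power(x, snr_db))
    n = np.arange(len(x))
    return amp * np.cos(2.0 * np.pi * f * n / fs)


def pacemaker_spikes(x: np.ndarray, snr_db: float, f: float,
                     qrs_onsets: list[int] | np.ndarray,
                     width: int = 1, lead_time: int = 1) -> np.ndarray:
    """Spikes of height ``sqrt(P_n / f)`` just before each QRS onset.

    ``width`` samples ending ``lead_time`` samples before the onset, so
    spike-like noise appears where a pacemaker would fire.
    """
    amp = np.sqrt(noise_power(x, snr_db) / f)
    noise = np.zeros(len(x))
    for onset in qrs_onsets:
        stop = max(int(onset) - lead_time + 1, 0)
        start = max(stop - width, 0)
        noise[start:stop] = amp
    return noise


def jitter_hyperparameter(value: float, snr_db: float,
                          seed: int | np.random.Generator = 0,
                          enabled: bool = True) -> float:
    """Perturb a generation hyperparameter by U(-SNR/10, +SNR/10)."""
    if not enabled:
        return value
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return value + rng.uniform(-snr_db / 10.0, snr_db / 10.0)


@dataclass(frozen=True)
class NoiseSpec:
    """One noise source with its generation hyperparameters."""

    kind: str
    snr_db: float = 20.0
    f: float | None = None  # RS rate / PN / BW frequency (Hz)
    p: float = 0.8  # AS saturation proportion
    jitter: bool = True

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.kind == "AS" and not 0.0 < self.p <= 1.0:
            raise ValueError("AS saturation proportion must be in (0, 1]")

    def default_f(self) -> float:
        if self.f is not None:
            return self.f
        return {"PN": 50.0, "BW": 0.5, "RS": 1.0, "PS": 1.0}.get(self.kind, 1.0)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Independent application of noise sources, capped in concurrency.

    Default: each of the six sources with probability 0.25, at most three at
    once, per-source SNR drawn uniformly from ``snr_range`` — keeps augmented
    signals recognizable while covering the noise taxonomy.
    """

    sources: tuple[tuple[NoiseSpec, float], ...] = tuple(
        (NoiseSpec(kind=k), 0.25) for k in NOISE_KINDS)
    max_concurrent: int = 3
    snr_range: tuple[float, float] = DEFAULT_SNR_RANGE

    def __post_init__(self):
        for spec, prob in self.sources:
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"application probability must be in [0, 1], got {prob}")


def generate_noise(spec: NoiseSpec, x: np.ndarray, fs: float,
                   rng: np.random.Generator,
                   qrs_onsets: list[int] | None = None,
                   snr_db: float | None = None) -> np.ndarray:
    """Dispatch one noise source; hyperparameters jittered when enabled."""
    snr = spec.snr_db if snr_db is None else snr_db
    f = spec.default_f()
    if spec.jitter:
        snr = jitter_hyperparameter(snr, snr, rng)
        if spec.kind in ("RS", "PN", "BW", "PS"):
            f = max(jitter_hyperparameter(f, snr, rng), 1.0 / (len(x) / fs))
    if spec.kind == "AWGN":
        return awgn(x, snr, rng)
    if spec.kind == "RS":
        return random_spikes(x, snr, min(f, fs / 2.0 - 1e-9), fs, rng)
    if spec.kind == "AS":
        return amplifier_saturation(x, min(max(spec.p, 1e-3), 1.0))
    if spec.kind in ("PN", "BW"):
        return sinusoid_noise(x, snr, min(f, fs / 2.0 - 1e-9), fs)
    if spec.kind == "PS":
        return pacemaker_spikes(x, snr, f, qrs_onsets if qrs_onsets is not None else [])
    raise ValueError(f"unknown noise kind {spec.kind!r}")  # pragma: no cover


def augment(x: np.ndarray, fs: float, policy: AugmentationPolicy,
            seed: int | np.random.Generator = 0,
            qrs_onsets: list[int] | None = None,
            draw_snr: bool = False) -> np.ndarray:
    """Apply a policy to one lead; returns the augmented lead.

    Each source passes an independent probability coin-flip, up to
    ``max_concurrent`` concurrent sources (first-come order).  With
    ``draw_snr`` the SNR of each applied source is drawn uniformly from the
    policy's range instead of the NoiseSpec's fixed value.  Fiducials are never
    modified: labels are noise-invariant.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = x.astype(np.float64).copy()
    applied = 0
    for spec, prob in policy.sources:
        if applied >= policy.max_concurrent:
            break
        if rng.random() >= prob:
            continue
        snr = rng.uniform(*policy.snr_range) if draw_snr else None
        y = y + generate_noise(spec, x, fs, rng, qrs_onsets=qrs_onsets, snr_db=snr)
        applied += 1
    return y
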