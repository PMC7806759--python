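"""Synthetic multi-lead ECG-like records with exactly known fiducials.

Each beat is a sum of smooth Gaussian deflections — one for the P wave, three
alternating-sign ones for the QRS complex, one wider one for the T wave — so
the ground-truth onset/peak/offset of every wave is known by construction: a
wave's onset (offset) is the first (last) sample where its own component
exceeds 5% of the component's peak magnitude, and the peak is the component's
extremal sample.  Leads are affine projections of one source beat train plus
small independent noise, which reproduces the inter-lead redundancy of
two-lead ambulatory recordings (and is why subject-wise splitting matters).

A degraded "low-quality" label variant (:func:`degrade_labels`) emulates
automatic single-lead annotators: boundaries are jittered, waves are dropped
at random and occasional spurious waves appear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ecg_io import ECGRecord, FiducialSet, WAVES, Beat, WaveFiducials

#: a wave "occupies" the samples where its component exceeds this fraction of
#: the component's own peak magnitude
ONSET_THRESHOLD = 0.05

# Gaussian geometry: component magnitude crosses ONSET_THRESHOLD at
# +/- sigma * sqrt(2 ln 20) ~ 2.448 sigma; widths are specified as the
# 5%-to-5% duration, so sigma = width / (2 * 2.448).
_SIGMA_PER_WIDTH = 1.0 / (2.0 * math.sqrt(2.0 * math.log(1.0 / ONSET_THRESHOLD)))
_ENVELOPE_SIGMAS = 4.0  # component is < 5% of peak outside +/- 4 sigma


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of one beat; amplitudes in mV, durations/intervals in ms."""

    p_amp: float = 0.15
    p_width: float = 90.0
    qrs_amps: tuple[float, float, float] = (-0.15, 1.0, -0.25)  # Q, R, S
    qrs_width: float = 90.0
    t_amp: float = 0.3
    t_width: float = 180.0
    pq_interval: float = 60.0  # gap between P offset and QRS onset
    st_interval: float = 110.0  # gap between QRS offset and T onset

    def __post_init__(self):
        for name in ("p_width", "qrs_width", "t_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pq_interval", "st_interval"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.qrs_amps) != 3:
            raise ValueError("qrs_amps must hold Q, R and S deflection amplitudes")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    n_subjects: int = 20
    n_leads: int = 2
    fs: float = 250.0
    duration: float = 30.0  # seconds per record
    heart_rate: float = 60.0  # bpm
    heart_rate_jitter: float = 0.05  # fractional per-beat RR jitter
    template: BeatTemplate = field(default_factory=BeatTemplate)
    template_variability: float = 0.1  # fractional per-beat morphology jitter
    missing_p_probability: float = 0.05
    lead_noise_mv: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_subjects < 1 or self.n_leads < 1:
            raise ValueError("need at least one subject and one lead")
        for name in ("heart_rate_jitter", "template_variability", "missing_p_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def _gaussian(t: np.ndarray, amp: float, center: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def generate_beat(template: BeatTemplate, fs: float) -> tuple[np.ndarray, Beat]:
    """One beat waveform (mV) and its nine ground-truth fiducials.

    Deterministic: the same template and sampling rate give bit-identical
    output.  A wave with zero amplitude is absent from the fiducial dict.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    s = 1e-3  # ms -> s
    sig_p = template.p_width * s * _SIGMA_PER_WIDTH
    sig_qrs = template.qrs_width * s * _SIGMA_PER_WIDTH * 0.6  # sub-deflections are narrow
    sig_t = template.t_width * s * _SIGMA_PER_WIDTH
    d_qrs = 0.3 * template.qrs_width * s  # Q/S center offset from R

    has_p = template.p_amp != 0.0
    has_qrs = any(a != 0.0 for a in template.qrs_amps)
    has_t = template.t_amp != 0.0

    # Sequential layout using conservative +/- 4 sigma envelopes, so the 5%
    # crossings of consecutive waves can never reorder.
    h_p = _ENVELOPE_SIGMAS * sig_p
    h_qrs = d_qrs + _ENVELOPE_SIGMAS * sig_qrs
    h_t = _ENVELOPE_SIGMAS * sig_t
    cursor = 0.0
    c_p = c_qrs = c_t = 0.0
    if has_p:
        c_p = cursor + h_p
        cursor = c_p + h_p + template.pq_interval * s
    if has_qrs:
        c_qrs = cursor + h_qrs
        cursor = c_qrs + h_qrs + template.st_interval * s
    if has_t:
        c_t = cursor + h_t
        cursor = c_t + h_t
    n = int(math.ceil(cursor * fs)) + 1
    t = np.arange(n) / fs

    components: dict[str, np.ndarray] = {}
    if has_p:
        components["P"] = _gaussian(t, template.p_amp, c_p, sig_p)
    if has_qrs:
        q, r, sdefl = template.qrs_amps
        components["QRS"] = (_gaussian(t, q, c_qrs - d_qrs, sig_qrs)
                             + _gaussian(t, r, c_qrs, sig_qrs)
                             + _gaussian(t, sdefl, c_qrs + d_qrs, sig_qrs))
    if has_t:
        components["T"] = _gaussian(t, template.t_amp, c_t, sig_t)

    waveform = np.zeros(n)
    beat: Beat = {}
    for wave in WAVES:
        if wave not in components:
            continue
        comp = components[wave]
        waveform += comp
        mag = np.abs(comp)
        above = np.flatnonzero(mag >= ONSET_THRESHOLD * mag.max())
        beat[wave] = WaveFiducials(int(above[0]), int(np.argmax(mag)), int(above[-1]))
    return waveform, beat


def _perturbed_template(template: BeatTemplate, variability: float,
                        rng: np.random.Generator) -> BeatTemplate:
    def jit() -> float:
        return 1.0 + rng.uniform(-variability, variability)

    return replace(
        template,
        p_amp=template.p_amp * jit(),
        p_width=template.p_width * jit(),
        qrs_amps=tuple(a * jit() for a in template.qrs_amps),
        qrs_width=template.qrs_width * jit(),
        t_amp=template.t_amp * jit(),
        t_width=template.t_width * jit(),
        pq_interval=template.pq_interval * jit(),
        st_interval=template.st_interval * jit(),
    )


def generate_record(spec: SimulationSpec, record_id: str = "sub000",
                    rng: np.random.Generator | None = None
                    ) -> tuple[ECGRecord, FiducialSet]:
    """One multi-lead record with beats at jittered RR intervals.

    All leads share the same ground-truth fiducials (multi-lead truth); each
    lead is a scaled, possibly sign-flipped projection of one source train
    plus small independent Gaussian noise.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.duration * spec.fs))
    base_rr = 60.0 / spec.heart_rate  # seconds

    source = np.zeros(n_total)
    beats: list[Beat] = []
    cursor = 0  # sample index of current beat start
    while True:
        tpl = _perturbed_template(spec.template, spec.template_variability, rng)
        if rng.random() < spec.missing_p_probability:
            tpl = replace(tpl, p_amp=0.0)
        waveform, beat = generate_beat(tpl, spec.fs)
        if cursor + waveform.size > n_total:
            break
        source[cursor:cursor + waveform.size] += waveform
        beats.append({w: wf.shifted(cursor) for w, wf in beat.items()})
        rr = base_rr * (1.0 + spec.heart_rate_jitter * rng.standard_normal())
        step = max(int(round(rr * spec.fs)), waveform.size + 1)
        cursor += step
    if not beats:
        raise ValueError(
            f"duration {spec.duration}s too short for a single beat at fs={spec.fs}")

    signal = np.empty((n_total, spec.n_leads))
    for lead in range(spec.n_leads):
        if lead == 0:
            scale = 1.0
        else:
            scale = rng.uniform(0.5, 1.0) * (-1.0 if rng.random() < 0.3 else 1.0)
        signal[:, lead] = scale * source + spec.lead_noise_mv * rng.standard_normal(n_total)

    record = ECGRecord(record_id=record_id, fs=spec.fs, signal=signal)
    fiducials = FiducialSet(record_id=record_id,
                            leads=[[dict(b) for b in beats] for _ in range(spec.n_leads)])
    fiducials.validate(n_total)
    return record, fiducials


def generate_dataset(spec: SimulationSpec) -> list[tuple[ECGRecord, FiducialSet]]:
    """``spec.n_subjects`` independent records, reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_subjects):
        sub_rng = np.random.default_rng(rng.integers(0, 2 ** 31))
        out.append(generate_record(spec, record_id=f"sub{i:03d}", rng=sub_rng))
    return out


def degrade_labels(fiducials: FiducialSet, fs: float, onset_noise_sd: float = 8.0,
                   miss_rate: float = 0.1, false_rate: float = 0.05,
                   seed: int = 0) -> FiducialSet:
    """Emulate automatic single-lead labels from clean fiducials.

    Boundaries (on, peak, off) are independently jittered with Gaussian noise
    of ``onset_noise_sd`` milliseconds and re-sorted so ``on <= peak <= off``;
    each wave is dropped with probability ``miss_rate``; with probability
    ``false_rate`` per inter-beat gap a short spurious wave is inserted.
    Beat-overlap invariants are restored by clipping against neighbours.
    """
    for name, rate in (("miss_rate", miss_rate), ("false_rate", false_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sd_samples = onset_noise_sd * fs / 1000.0

    def jitter(wf: WaveFiducials) -> WaveFiducials:
        if sd_samples == 0:
            return wf
        vals = sorted(int(round(v + rng.normal(0.0, sd_samples)))
                      for v in (wf.on, wf.peak, wf.off))
        return WaveFiducials(*(max(0, v) for v in vals))

    new_leads: list[list[Beat]] = []
    for beats in fiducials.leads:
        out_beats: list[Beat] = []
        prev_off = -1
        for beat in beats:
            new_beat: Beat = {}
            for wave in WAVES:
                if wave not in beat:
                    continue
                if miss_rate > 0 and rng.random() < miss_rate:
                    continue
                wf = jitter(beat[wave])
                if wf.on <= prev_off:  # clip against the previous wave
                    on = prev_off + 1
                    if on > wf.off:
                        continue
                    wf = WaveFiducials(on, max(on, wf.peak), wf.off)
                new_beat[wave] = wf
                prev_off = wf.off
            if new_beat:
                out_beats.append(new_beat)
        # spurious waves in inter-beat gaps
        if false_rate > 0 and out_beats:
            final: list[Beat] = []
            for i, beat in enumerate(out_beats):
                final.append(beat)
                if i + 1 < len(out_beats) and rng.random() < false_rate:
                    gap_lo = max(beat[w].off for w in beat) + 2
                    nxt = out_beats[i + 1]
                    gap_hi = min(nxt[w].on for w in nxt) - 2
                    width = int(round(0.06 * fs))  # ~60 ms blip
                    if gap_hi - gap_lo > width + 2:
                        on = int(rng.integers(gap_lo, gap_hi - width))
                        wave = WAVES[int(rng.integers(0, 3))]
                        final.append({wave: WaveFiducials(on, on + width // 2, on + width)})
            out_beats = final
        new_leads.append(out_beats)
    return FiducialSet(record_id=fiducials.record_id, leads=new_leads)
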