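"""Reading and writing ECG signals and per-beat wave annotations.

Signals use a minimal WFDB dialect: a text ``.hea`` header plus a little-endian
int16 ``.dat`` file (format 16) with per-lead gain and baseline, so records stay
interoperable with PhysioNet tooling.  Annotations are stored as a text table of
``sample symbol chan`` rows following the usual annotation conventions:
``(`` marks a wave onset, ``)`` an offset, and ``p`` / ``N`` / ``t`` the P, QRS
and T peaks.  Synthetic ground truth can additionally round-trip through a JSON
sidecar.

The in-memory containers — :class:`ECGRecord` and :class:`FiducialSet` — are
shared by every other module.  Sample indexing is 0-based and wave intervals
``[on, off]`` are closed on both ends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger("ecgdelnet")

WAVES = ("P", "QRS", "T")

#: annotation peak symbol per wave type
PEAK_SYMBOLS = {"P": "p", "QRS": "N", "T": "t"}
_SYMBOL_TO_WAVE = {v: k for k, v in PEAK_SYMBOLS.items()}


@dataclass(frozen=True)
class WaveFiducials:
    """Onset, peak and offset sample indices of one wave (closed interval)."""

    on: int
    peak: int
    off: int

    def __post_init__(self):
        if not (self.on <= self.peak <= self.off):
            raise ValueError(f"fiducials out of order: {self.on}, {self.peak}, {self.off}")

    def shifted(self, offset: int) -> "WaveFiducials":
        return WaveFiducials(self.on + offset, self.peak + offset, self.off + offset)


#: one beat: mapping from wave name ("P", "QRS", "T") to its fiducials; a wave
#: may be absent (e.g. missing P).
Beat = dict


@dataclass
class ECGRecord:
    """A multi-lead sampled ECG voltage signal in mV."""

    record_id: str
    fs: float
    signal: np.ndarray  # samples x leads
    lead_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.signal.ndim != 2:
            raise ValueError("signal must be a samples x leads matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.lead_names:
            self.lead_names = [f"lead{i}" for i in range(self.n_leads)]
        if len(self.lead_names) != self.n_leads:
            raise ValueError("lead_names length must match number of leads")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]


@dataclass
class FiducialSet:
    """Per-lead, per-beat wave fiducials for one record.

    ``leads[l]`` is an ordered list of beats; each beat maps wave names to
    :class:`WaveFiducials`.  Within a beat waves are ordered P -> QRS -> T and
    do not overlap.
    """

    record_id: str
    leads: list[list[Beat]]

    def n_leads(self) -> int:
        return len(self.leads)

    def wave_list(self, lead: int, wave: str) -> list[WaveFiducials]:
        """All fiducials of one wave type on one lead, ordered by onset."""
        return [beat[wave] for beat in self.leads[lead] if wave in beat]

    def n_waves(self, wave: str) -> int:
        return sum(len(self.wave_list(lead, wave)) for lead in range(self.n_leads()))

    def validate(self, n_samples: int | None = None) -> None:
        """Raise ValueError on any ordering/overlap/range violation."""
        for l, beats in enumerate(self.leads):
            prev_end = -1
            for b, beat in enumerate(beats):
                present = [w for w in WAVES if w in beat]
                for w in present:
                    wf = beat[w]
                    if wf.on < 0:
                        raise ValueError(f"lead {l} beat {b} {w}: negative sample")
                    if n_samples is not None and wf.off >= n_samples:
                        raise ValueError(
                            f"lead {l} beat {b} {w}: offset {wf.off} beyond record "
                            f"length {n_samples}")
                for w1, w2 in zip(present[:-1], present[1:]):
                    if beat[w1].off >= beat[w2].on:
                        raise ValueError(
                            f"lead {l} beat {b}: {w1} and {w2} overlap or out of order")
                if present:
                    if beat[present[0]].on <= prev_end:
                        raise ValueError(f"lead {l} beat {b}: overlaps previous beat")
                    prev_end = beat[present[-1]].off

    # --- JSON sidecar -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "record_id": self.record_id,
            "leads": [
                [{w: [beat[w].on, beat[w].peak, beat[w].off] for w in beat} for beat in beats]
                for beats in self.leads
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FiducialSet":
        payload = json.loads(Path(path).read_text())
        leads = [
            [{w: WaveFiducials(*map(int, v)) for w, v in beat.items()} for beat in beats]
            for beats in payload["leads"]
        ]
        return cls(record_id=payload["record_id"], leads=leads)


@dataclass
class DatasetManifest:
    """Index of a dataset on disk: one entry per (record, label-quality)."""

    entries: list[dict]  # record_id, signal, annotations, quality (high|low)

    def __post_init__(self):
        for e in self.entries:
            if e.get("quality") not in ("high", "low"):
                raise ValueError(f"entry {e.get('record_id')}: quality must be high|low")

    def record_ids(self) -> list[str]:
        return sorted({e["record_id"] for e in self.entries})

    def for_quality(self, quality: str) -> list[dict]:
        return [e for e in self.entries if e["quality"] == quality]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"records": self.entries}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(entries=payload["records"])


# --------------------------------------------------------------------------
# WFDB-dialect signal files
# --------------------------------------------------------------------------

_DEFAULT_GAIN = 1000.0  # ADC units per mV -> microvolt resolution


def write_record(record: ECGRecord, directory: str | Path) -> Path:
    """Write ``<record_id>.hea`` + ``<record_id>.dat`` (format 16, int16)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hea = directory / f"{record.record_id}.hea"
    dat_name = f"{record.record_id}.dat"
    adc = np.clip(np.round(record.signal * _DEFAULT_GAIN), -32768, 32767).astype("<i2")
    lines = [f"{record.record_id} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for i, name in enumerate(record.lead_names):
        lines.append(f"{dat_name} 16 {_DEFAULT_GAIN:g}(0)/mV 16 0 {adc[0, i]} 0 0 {name}")
    hea.write_text("\n".join(lines) + "\n")
    (directory / dat_name).write_bytes(adc.reshape(-1).tobytes())
    return hea


def read_record(path: str | Path) -> ECGRecord:
    """Read a record from its ``.hea`` header path (or basename without suffix)."""
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise IOError(f"header file not found: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record_id, n_leads, fs, n_samples = head[0], int(head[1]), float(head[2]), int(head[3])
    gains, baselines, names, dat_name = [], [], [], None
    for ln in lines[1:1 + n_leads]:
        fields = ln.split()
        dat_name = fields[0]
        gain_field = fields[2].split("/")[0]
        if "(" in gain_field:
            gain, baseline = gain_field.rstrip(")").split("(")
        else:
            gain, baseline = gain_field, "0"
        gains.append(float(gain))
        baselines.append(float(baseline))
        names.append(fields[-1])
    dat_path = path.parent / dat_name
    if not dat_path.exists():
        raise IOError(f"signal file not found: {dat_path}")
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if raw.size != n_samples * n_leads:
        raise IOError(
            f"truncated signal file {dat_path}: expected {n_samples * n_leads} samples, "
            f"found {raw.size}")
    adc = raw.reshape(n_samples, n_leads).astype(np.float64)
    signal = (adc - np.asarray(baselines)) / np.asarray(gains)
    return ECGRecord(record_id=record_id, fs=fs, signal=signal, lead_names=names)


# --------------------------------------------------------------------------
# Annotation files
# --------------------------------------------------------------------------

def write_annotations(fiducials: FiducialSet, path: str | Path) -> Path:
    """Write a ``sample symbol chan`` text annotation table."""
    rows: list[tuple[int, str, int]] = []
    for chan, beats in enumerate(fiducials.leads):
        for beat in beats:
            for w in WAVES:
                if w in beat:
                    wf = beat[w]
                    rows.append((wf.on, "(", chan))
                    rows.append((wf.peak, PEAK_SYMBOLS[w], chan))
                    rows.append((wf.off, ")", chan))
    rows.sort(key=lambda r: (r[2], r[0]))
    path = Path(path)
    path.write_text("".join(f"{s} {sym} {chan}\n" for s, sym, chan in rows))
    return path


def read_annotations(path: str | Path, record: ECGRecord) -> FiducialSet:
    """Assemble beats from an annotation stream.

    Waves missing their onset or offset are dropped (isolated delineations are
    unusable for training); unknown symbols are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"annotation file not found: {path}")
    per_chan: dict[int, list[tuple[int, str]]] = {}
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split()
        sample, symbol = int(fields[0]), fields[1]
        chan = int(fields[2]) if len(fields) > 2 else 0
        if sample < 0 or sample >= record.n_samples:
            raise ValueError(f"{path}: sample {sample} outside record of "
                             f"length {record.n_samples}")
        per_chan.setdefault(chan, []).append((sample, symbol))

    n_leads = record.n_leads
    leads: list[list[Beat]] = [[] for _ in range(n_leads)]
    for chan, events in per_chan.items():
        if chan >= n_leads:
            raise ValueError(f"{path}: channel {chan} beyond record leads")
        waves = _assemble_waves(events, path)
        leads[chan] = _group_beats(waves)
    fids = FiducialSet(record_id=record.record_id, leads=leads)
    fids.validate(record.n_samples)
    return fids


def _assemble_waves(events: list[tuple[int, str]], path: Path) -> list[tuple[str, WaveFiducials]]:
    waves = []
    pending_on: int | None = None
    pending: tuple[str, int] | None = None  # (wave, peak) awaiting its offset
    for sample, symbol in sorted(events):
        if symbol == "(":
            pending_on = sample
            pending = None
        elif symbol in _SYMBOL_TO_WAVE:
            pending = (_SYMBOL_TO_WAVE[symbol], sample)
        elif symbol == ")":
            if pending is not None and pending_on is not None:
                wave, peak = pending
                waves.append((wave, WaveFiducials(pending_on, peak, sample)))
            pending_on = None
            pending = None
        else:
            logger.warning("%s: skipping unknown annotation symbol %r at %d",
                           path, symbol, sample)
    return waves


def _group_beats(waves: list[tuple[str, WaveFiducials]]) -> list[Beat]:
    """Group an ordered wave stream into beats at each P->QRS (or QRS) boundary."""
    beats: list[Beat] = []
    current: Beat = {}
    order = {w: i for i, w in enumerate(WAVES)}
    last = -1
    for wave, wf in waves:
        if wave in current or order[wave] <= last:
            beats.append(current)
            current = {}
        current[wave] = wf
        last = order[wave]
    if current:
        beats.append(current)
    return beats


# --------------------------------------------------------------------------
# Run configuration / logging
# --------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"config file not found: {path}")
    return yaml.safe_load(path.read_text()) or {}


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=level, handlers=handlers,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
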