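import numpy as np
import pytest

from ecgdelnet import BeatTemplate, SimulationSpec, generate_record
from ecgdelnet.training import LabelledRecord


@pytest.fixture
def template():
    return BeatTemplate()


@pytest.fixture
def small_record():
    """One 2-lead 10 s synthetic record with known fiducials."""
    spec = SimulationSpec(n_subjects=1, n_leads=2, duration=10.0, seed=42,
                          missing_p_probability=0.0)
    record, fiducials = generate_record(spec)
    return record, fiducials


@pytest.fixture
def labelled(small_record):
    record, fiducials = small_record
    return LabelledRecord(record=record, fiducials=fiducials)


def random_wave_list(rng, n_samples, max_waves=6, min_len=3, max_len=30):
    """Ordered, non-overlapping random (on, peak, off) fiducials on one channel."""
    from ecgdelnet.ecg_io import WaveFiducials

    waves = []
    cursor = 0
    for _ in range(rng.integers(0, max_waves + 1)):
        gap = int(rng.integers(1, 40))
        length = int(rng.integers(min_len, max_len))
        on = cursor + gap
        off = on + length - 1
        if off >= n_samples:
            break
        peak = int(rng.integers(on, off + 1))
        waves.append(WaveFiducials(on, peak, off))
        cursor = off + 1
    return waves
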