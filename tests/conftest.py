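import numpy as np
import pytest

import circabehave as cb


@pytest.fixture
def ld():
    return cb.LightSchedule.ld()


@pytest.fixture
def dd():
    return cb.LightSchedule.dd()


@pytest.fixture
def skeleton():
    return cb.LightSchedule.skeleton()


def square_wave_record(
    n_days=10,
    bin_minutes=3.0,
    onset_min=720.0,
    duration_min=720.0,
    level=10.0,
    schedule=None,
):
    """Noiseless bin-aligned square-wave actogram (onset/duration on the bin grid)."""
    schedule = schedule or cb.LightSchedule.ld()
    bpd = int(round(1440.0 / bin_minutes))
    starts = np.arange(bpd) * bin_minutes
    active = ((starts - onset_min) % 1440.0) < duration_min
    day = np.where(active, level, 0.0)
    return cb.ActivityRecord(np.tile(day, n_days), bin_minutes, 0.0, schedule)


def chunked_immobility(rng, n_seconds, lo=0.8, hi=1.0, max_chunk=60):
    """Piecewise-constant immobility trace with run lengths straddling 40 s."""
    vals = []
    while sum(len(v) for v in vals) < n_seconds:
        k = int(rng.integers(1, max_chunk + 1))
        vals.append(np.full(k, rng.uniform(lo, hi)))
    return np.concatenate(vals)[:n_seconds]
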