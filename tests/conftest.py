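import numpy as np
import pytest

from wavecoh.coherence import CoherenceMap
from wavecoh.preprocess import RegionMap
from wavecoh.synthetic import SignalRecord, TrialSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Cheap trial spec for simulation-backed tests."""
    return TrialSpec(duration_s=6.0, fs_hz=250.0, seed=3)


def map_from_mask(mask, dt=0.2, freqs=None, coh=None):
    """CoherenceMap around a given significance mask (uniform grids)."""
    mask = np.asarray(mask, dtype=bool)
    nf, nt = mask.shape
    if freqs is None:
        freqs = np.linspace(3.0, 30.0, nf)
    times = np.arange(nt) * dt
    if coh is None:
        coh = np.where(mask, 0.9, 0.1)
    return CoherenceMap(times=times, freqs=np.asarray(freqs, dtype=float),
                        coh=np.asarray(coh, dtype=float), sig_mask=mask)


def electrode_record(duration_s=4.0, fs=1000.0, seed=0, extra=("force",)):
    """A 63-electrode record matching the default region map, plus
    pass-through channels."""
    rng = np.random.default_rng(seed)
    names = RegionMap().all_channels + list(extra)
    n = int(duration_s * fs)
    return SignalRecord(
        subject_id="A", trial_id="t1", task="PIMA", fs_hz=fs,
        channel_names=names, samples=rng.standard_normal((len(names), n)),
        triggers=(0.0, 0.2 * duration_s, 0.9 * duration_s),
    )
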