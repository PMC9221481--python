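"""Synthetic two-subject coupled recordings.

Generates surrogate studies with the statistical structure the coherence
analysis assumes: mechanical muscle oscillations near 10 Hz with a shared,
phase-jittered drive of configurable coupling strength; EEG-like channels
with a 1/f background plus an alpha-band rhythm; and force/acceleration
channels recorded by a single physical sensor and therefore identical in
both partners' records.

The generator emulates the *statistical* features the downstream estimators
rely on (narrowband ~10 Hz muscle rhythm, cross-subject phase locking,
broadband EEG background), not the biomechanics of real isometric trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidSpecError

TASKS = ("HIMA", "PIMA", "MVIC", "OpEy")

#: channel layout of one subject's record (10 EEG sub-regions, 3 MMG/MTG
#: channels, shared force and acceleration sensors)
EEG_CHANNELS = ("FM", "C", "CP", "POc", "AFle", "TLle", "POle", "AFri", "TLri", "POri")
MMG_CHANNELS = ("MMGtri", "MTGtri", "MMGobl")
SHARED_CHANNELS = ("force", "ACC")


@dataclass(frozen=True)
class TrialSpec:
    """Parameters of one simulated coupled trial.

    ``coupling`` in [0, 1] is the fraction of each muscle channel's rhythm
    variance contributed by the shared oscillator (mixed with amplitude
    sqrt(coupling)); the complement comes from a subject-private oscillator
    of the same kind, so uncoupled subjects still oscillate near
    ``osc_freq_hz`` but independently.
    """

    duration_s: float = 30.0
    fs_hz: float = 1000.0
    osc_freq_hz: float = 10.0
    coupling: float = 0.8
    phase_jitter_sd: float = 0.05  # radians per step at the 1 kHz reference rate
    alpha_band: tuple[float, float] = (8.0, 15.0)
    one_over_f_exp: float = 1.0
    mmg_snr_db: float = 6.0
    eeg_snr_db: float = 0.0
    seed: int = 0
    task_a: str = "PIMA"
    task_b: str = "HIMA"

    def validate(self) -> None:
        if self.duration_s < 3.0:
            raise InvalidSpecError(f"duration_s={self.duration_s} < 3 s minimum usable trial")
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise InvalidSpecError("fs_hz and duration_s must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise InvalidSpecError(f"coupling={self.coupling} outside [0, 1]")
        if self.fs_hz <= 2.0 * self.osc_freq_hz:
            raise InvalidSpecError("fs_hz must exceed twice osc_freq_hz")
        if self.task_a not in TASKS or self.task_b not in TASKS:
            raise InvalidSpecError(f"tasks must be one of {TASKS}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


@dataclass
class SignalRecord:
    """One trial's multichannel samples for one subject."""

    subject_id: str
    trial_id: str
    task: str
    fs_hz: float
    channel_names: list[str]
    samples: np.ndarray  # channels x time
    triggers: tuple[float, float, float]  # t1 <= t2 < t3, seconds

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channel_names):
            raise InvalidSpecError("one channel name per sample row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidSpecError("channel names must be unique")
        t1, t2, t3 = self.triggers
        if not (t1 <= t2 < t3):
            raise InvalidSpecError(f"triggers must satisfy t1 <= t2 < t3, got {self.triggers}")
        if t3 > self.duration_s + 1.0 / self.fs_hz:
            raise InvalidSpecError("trigger t3 beyond record duration")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


def make_shared_oscillator(spec: TrialSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Unit-variance narrowband oscillation at ``osc_freq_hz`` with random-walk
    phase jitter; the common drive both subjects couple to."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    dt = 1.0 / spec.fs_hz
    # uniform initial phase: independently generated oscillators must not
    # share a phase reference
    phase = 2.0 * np.pi * spec.osc_freq_hz * dt * np.arange(n) + rng.uniform(0.0, 2.0 * np.pi)
    if spec.phase_jitter_sd > 0:
        # scale the per-step jitter so the phase diffusion RATE (rad^2/s) is
        # independent of the generation sampling rate
        sd_step = spec.phase_jitter_sd * np.sqrt(1000.0 / spec.fs_hz)
        phase = phase + np.cumsum(rng.normal(0.0, sd_step, n))
    x = np.cos(phase)
    return x / x.std()


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity; DC is zeroed below
    spectrum *= f ** (-exponent / 2.0)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n)
    return x / x.std()


def _alpha_rhythm(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Band-limited EEG rhythm: white noise filtered to the alpha band."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def make_trial_pair(spec: TrialSpec, trial_id: str = "trial1") -> tuple[SignalRecord, SignalRecord]:
    """Generate the two subjects' records of one coupled trial.

    Each record carries 10 EEG-region-like channels, 3 MMG-like channels and
    the shared force/ACC channels; triggers are placed at 0 %, 5 % and 95 %
    of the duration (only the t2->t3 cut matters downstream).
    """
    spec.validate()
    root = np.random.default_rng(spec.seed)
    streams = root.spawn(4)  # shared drive, subject A, subject B, sensors
    shared = make_shared_oscillator(spec, streams[0])
    n = spec.n_samples
    mmg_noise_amp = 10.0 ** (-spec.mmg_snr_db / 20.0)
    eeg_gain = 10.0 ** (spec.eeg_snr_db / 20.0)

    # amplitude weights sqrt(c), sqrt(1-c): coupling is the VARIANCE fraction
    # of the shared drive, so it is directly identifiable from coherence
    w_shared = np.sqrt(spec.coupling)
    w_own = np.sqrt(1.0 - spec.coupling)

    def build_subject(subject_id: str, task: str, rng: np.random.Generator) -> SignalRecord:
        own = make_shared_oscillator(replace(spec, seed=0), rng)
        rows = []
        for _ in EEG_CHANNELS:
            bg = _one_over_f_noise(n, spec.one_over_f_exp, rng)
            alpha = _alpha_rhythm(n, spec.fs_hz, spec.alpha_band, rng)
            rows.append(bg + 0.5 * alpha + w_shared * eeg_gain * shared)
        for _ in MMG_CHANNELS:
            noise = mmg_noise_amp * rng.standard_normal(n)
            rows.append(w_shared * shared + w_own * own + noise)
        return SignalRecord(
            subject_id=subject_id,
            trial_id=trial_id,
            task=task,
            fs_hz=spec.fs_hz,
            channel_names=list(EEG_CHANNELS) + list(MMG_CHANNELS) + list(SHARED_CHANNELS),
            samples=np.vstack(rows + [np.zeros((2, n))]),
            triggers=(0.0, 0.05 * spec.duration_s, 0.95 * spec.duration_s),
        )

    rec_a = build_subject("A", spec.task_a, streams[1])
    rec_b = build_subject("B", spec.task_b, streams[2])
    # one physical strain gauge / accelerometer serves both partners
    sensor_rng = streams[3]
    force = shared + 0.2 * sensor_rng.standard_normal(n)
    acc = shared + 0.2 * sensor_rng.standard_normal(n)
    for rec in (rec_a, rec_b):
        rec.samples[rec.channel_names.index("force")] = force
        rec.samples[rec.channel_names.index("ACC")] = acc
    return rec_a, rec_b


def make_study(
    spec: TrialSpec,
    n_trials: int = 6,
    alternate_tasks: bool = True,
) -> list[SignalRecord]:
    """Generate ``n_trials`` coupled trial pairs, alternating which partner
    pushes (PIMA) and which holds (HIMA), as in the fatiguing-trial design."""
    records: list[SignalRecord] = []
    for i in range(n_trials):
        task_a, task_b = spec.task_a, spec.task_b
        if alternate_tasks and i % 2 == 1:
            task_a, task_b = task_b, task_a
        trial_spec = replace(spec, seed=spec.seed + i, task_a=task_a, task_b=task_b)
        records.extend(make_trial_pair(trial_spec, trial_id=f"trial{i + 1}"))
    return records
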