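"""Signal conditioning: trial cutting, notch, bandpass, decimation, drift
removal and EEG sub-region averaging.

The fixed stage order is cut -> notch -> bandpass -> downsample -> drift
removal -> region averaging. The bandpass runs at the original 1 kHz rate
(its 256 Hz upper edge requires it); drift removal runs at the decimated
250 Hz rate. All filters are applied forward-backward (zero phase), so each
stage is linear and maps the zero signal to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError, InsufficientDurationError, MappingError, TriggerError
from .synthetic import SignalRecord

# The ten EEG sub-regions (10/20 electrode sets averaged sample-wise) and
# their grouping into the three statistics regions. CPz is the reference
# electrode and appears nowhere.
DEFAULT_SUBREGIONS: dict[str, list[str]] = {
    "FM": ["Fpz", "Fz"],
    "C": ["FC1", "FCz", "FC2", "C1", "Cz", "C2"],
    "CP": ["CP1", "CP2"],
    "POc": ["Pz", "POz", "Oz"],
    "AFle": ["Fp1", "AF3", "AF7", "F1", "F3", "F5", "F7"],
    "TLle": ["FC3", "FC5", "FT7", "C3", "C5", "T7", "CP3", "CP5", "TP7", "M1"],
    "POle": ["P1", "P3", "P5", "P7", "PO3", "PO5", "PO7", "O1"],
    "AFri": ["Fp2", "AF4", "AF8", "F2", "F4", "F6", "F8"],
    "TLri": ["FC4", "FC6", "FT8", "C4", "C6", "T8", "CP4", "CP6", "TP8", "M2"],
    "POri": ["P2", "P4", "P6", "P8", "PO4", "PO6", "PO8", "O2"],
}

DEFAULT_REGION_OF: dict[str, str] = {
    "FM": "EEGcen", "C": "EEGcen", "CP": "EEGcen", "POc": "EEGcen",
    "AFle": "EEGle", "TLle": "EEGle", "POle": "EEGle",
    "AFri": "EEGri", "TLri": "EEGri", "POri": "EEGri",
}


@dataclass(frozen=True)
class RegionMap:
    """Sub-region -> electrode channels, and sub-region -> statistics region."""

    subregions: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_SUBREGIONS))
    region_of: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REGION_OF))

    def validate(self) -> None:
        seen: set[str] = set()
        for name, channels in self.subregions.items():
            overlap = seen.intersection(channels)
            if overlap:
                raise ConfigError(f"channels {sorted(overlap)} assigned to two sub-regions")
            seen.update(channels)
        if "CPz" in seen:
            raise ConfigError("CPz is the reference electrode and cannot be mapped")
        missing = set(self.subregions) - set(self.region_of)
        if missing:
            raise ConfigError(f"sub-regions without statistics region: {sorted(missing)}")

    @property
    def all_channels(self) -> list[str]:
        return [ch for channels in self.subregions.values() for ch in channels]

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        """Load a user mapping file with ``subregions`` and ``region_of`` keys."""
        import yaml

        data = yaml.safe_load(open(path))
        rmap = cls(subregions=dict(data["subregions"]), region_of=dict(data["region_of"]))
        rmap.validate()
        return rmap


@dataclass(frozen=True)
class PreprocConfig:
    notch_band: tuple[float, float] = (49.0, 51.0)
    bandpass: tuple[float, float] = (0.016, 256.0)
    bandpass_taps: int = 25
    bandpass_method: str = "fir"  # "fir" (windowed-sinc, Hamming) or "butter"
    butter_order: int = 4
    downsample_to: float = 250.0
    drift_order: int = 10
    drift_cutoff_hz: float = 1.0
    antialias_cutoff_hz: float = 100.0
    min_trial_s: float = 3.0

    def validate(self, fs: float) -> None:
        lo, hi = self.notch_band
        if not (self.bandpass[0] < lo < hi < self.bandpass[1]):
            raise ConfigError("notch band must lie inside the bandpass")
        if hi >= fs / 2:
            raise ConfigError(f"notch band {self.notch_band} outside Nyquist for fs={fs}")
        if self.bandpass[1] >= fs / 2:
            raise ConfigError(
                f"bandpass upper edge {self.bandpass[1]} Hz >= Nyquist for fs={fs} Hz; "
                "apply the bandpass before downsampling"
            )
        if fs % self.downsample_to:
            raise ConfigError(f"downsample_to={self.downsample_to} must divide fs={fs}")
        if self.bandpass_method not in ("fir", "butter"):
            raise ConfigError(f"unknown bandpass method {self.bandpass_method!r}")


# --------------------------------------------------------------------------
# trial cutting


def cut_trial(record: SignalRecord, mode: str = "plateau", min_trial_s: float = 3.0) -> SignalRecord:
    """Cut a trial to its analysis window.

    plateau: keep [t2, t3], the isometric force plateau.
    mvic:    like plateau, but if t3 - t2 < ``min_trial_s`` the start is
             shifted earlier (bounded by t1) so at least ``min_trial_s`` is kept.
    full:    keep everything (resting/opened-eyes trials).
    """
    if mode == "full":
        return record
    if mode not in ("plateau", "mvic"):
        raise ConfigError(f"unknown cut mode {mode!r}")
    t1, t2, t3 = record.triggers
    if t3 <= t2:
        raise TriggerError(f"t3={t3} <= t2={t2}")
    start = t2
    if mode == "mvic" and t3 - t2 < min_trial_s:
        start = max(t1, t3 - min_trial_s)
        if t3 - start < min_trial_s - 0.5 / record.fs_hz:
            raise InsufficientDurationError(
                f"cannot extend MVIC window to {min_trial_s} s within [t1={t1}, t3={t3}]"
            )
    i0 = int(round(start * record.fs_hz))
    i1 = int(round(t3 * record.fs_hz))
    return SignalRecord(
        subject_id=record.subject_id,
        trial_id=record.trial_id,
        task=record.task,
        fs_hz=record.fs_hz,
        channel_names=list(record.channel_names),
        samples=record.samples[:, i0:i1],
        triggers=(0.0, 0.0, (i1 - i0) / record.fs_hz),
    )


def truncate_to_common_length(records: list[SignalRecord]) -> list[SignalRecord]:
    """Cut all records to the shortest one (keeping the start), as required
    before randomly re-pairing signals across trials."""
    if not records:
        raise ConfigError("no records to truncate")
    n_min = min(r.n_samples for r in records)
    out = []
    for r in records:
        if r.n_samples == n_min:
            out.append(r)
        else:
            t3 = min(r.triggers[2], n_min / r.fs_hz)
            out.append(
                SignalRecord(
                    subject_id=r.subject_id, trial_id=r.trial_id, task=r.task,
                    fs_hz=r.fs_hz, channel_names=list(r.channel_names),
                    samples=r.samples[:, :n_min],
                    triggers=(r.triggers[0], min(r.triggers[1], t3 - 1 / r.fs_hz), t3),
                )
            )
    return out


# --------------------------------------------------------------------------
# filters (arrays, last axis = time)


def notch_filter(x: np.ndarray, fs: float, band: tuple[float, float] = (49.0, 51.0)) -> np.ndarray:
    """Zero-phase second-order IIR notch centred on the band (power-line)."""
    lo, hi = band
    if hi >= fs / 2:
        raise ConfigError(f"notch band {band} outside Nyquist for fs={fs}")
    f0 = 0.5 * (lo + hi)
    b, a = sps.iirnotch(f0, Q=f0 / (hi - lo), fs=fs)
    return sps.filtfilt(b, a, x, axis=-1)


def bandpass_filter(x: np.ndarray, fs: float, config: PreprocConfig = PreprocConfig()) -> np.ndarray:
    """Zero-phase bandpass 0.016-256 Hz.

    Default is the 25-tap windowed-sinc FIR (Hamming window). Note such a
    short FIR cannot realise the 0.016 Hz edge, so it leaves DC essentially
    untouched; the dedicated drift-removal stage is what pulls the signals
    down to zero mean. The "butter" method is a conventional IIR Butterworth
    bandpass that does null DC.
    """
    lo, hi = config.bandpass
    if hi >= fs / 2:
        raise ConfigError(f"bandpass upper edge {hi} Hz >= Nyquist for fs={fs} Hz")
    if config.bandpass_method == "butter":
        sos = sps.butter(config.butter_order, (lo, hi), btype="bandpass", fs=fs, output="sos")
        return sps.sosfiltfilt(sos, x, axis=-1)
    taps = sps.firwin(config.bandpass_taps, (lo, hi), window="hamming", pass_zero=False, fs=fs)
    return sps.filtfilt(taps, [1.0], x, axis=-1)


def downsample(x: np.ndarray, from_hz: float, to_hz: float, antialias_cutoff_hz: float = 100.0) -> np.ndarray:
    """Decimate after an anti-alias lowpass (zero-phase FIR, cutoff below the
    target Nyquist)."""
    ratio = from_hz / to_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ConfigError(f"non-integer decimation ratio {from_hz}/{to_hz}")
    if q == 1:
        return np.asarray(x, dtype=float)
    if antialias_cutoff_hz >= to_hz / 2:  # must be below the new Nyquist
        raise ConfigError("anti-alias cutoff must be below the target Nyquist")
    taps = sps.firwin(101, antialias_cutoff_hz, window="hamming", fs=from_hz)
    filtered = sps.filtfilt(taps, [1.0], x, axis=-1)
    return filtered[..., ::q]


def remove_drift(x: np.ndarray, fs: float, order: int = 10, cutoff_hz: float = 1.0) -> np.ndarray:
    """Subtract the heavily low-passed signal (order-10 Butterworth, 1 Hz),
    pulling the trace down to oscillate around zero."""
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    # the 1 Hz lowpass has a long impulse response; extend the reflection
    # padding accordingly to keep edge transients small
    padlen = min(np.shape(x)[-1] - 1, int(3.0 * fs / cutoff_hz))
    return x - sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


# --------------------------------------------------------------------------
# region averaging and the full chain


def average_regions(record: SignalRecord, region_map: RegionMap | None = None) -> SignalRecord:
    """Average electrode channels sample-wise into the ten EEG sub-regions.

    Non-EEG channels present in the record (MMGs, force, ACC) are passed
    through unchanged after the region channels.
    """
    region_map = region_map or RegionMap()
    region_map.validate()
    mapped = set(region_map.all_channels)
    missing = mapped - set(record.channel_names)
    if missing:
        raise MappingError(f"record lacks mapped channels: {sorted(missing)}")
    names: list[str] = []
    rows: list[np.ndarray] = []
    for name, channels in region_map.subregions.items():
        idx = [record.channel_names.index(ch) for ch in channels]
        names.append(name)
        rows.append(record.samples[idx].mean(axis=0))
    for ch in record.channel_names:
        if ch not in mapped:
            names.append(ch)
            rows.append(record.channel(ch))
    return SignalRecord(
        subject_id=record.subject_id, trial_id=record.trial_id, task=record.task,
        fs_hz=record.fs_hz, channel_names=names, samples=np.vstack(rows),
        triggers=record.triggers,
    )


def preprocess_record(
    record: SignalRecord,
    config: PreprocConfig = PreprocConfig(),
    region_map: RegionMap | None = None,
    cut_mode: str | None = None,
) -> SignalRecord:
    """Run the full conditioning chain on one record.

    ``cut_mode`` defaults by task: plateau for HIMA/PIMA, mvic for MVIC,
    full for OpEy. Region averaging is applied only when the record contains
    raw electrode channels; records already at sub-region level pass through.
    """
    config.validate(record.fs_hz)
    if cut_mode is None:
        cut_mode = {"MVIC": "mvic", "OpEy": "full"}.get(record.task, "plateau")
    rec = cut_trial(record, cut_mode, config.min_trial_s)
    if rec.duration_s < config.min_trial_s:
        raise InsufficientDurationError(
            f"trial {rec.trial_id}/{rec.subject_id}: {rec.duration_s:.2f} s < {config.min_trial_s} s"
        )
    x = notch_filter(rec.samples, rec.fs_hz, config.notch_band)
    x = bandpass_filter(x, rec.fs_hz, config)
    x = downsample(x, rec.fs_hz, config.downsample_to, config.antialias_cutoff_hz)
    x = remove_drift(x, config.downsample_to, config.drift_order, config.drift_cutoff_hz)
    fs_new = config.downsample_to
    out = SignalRecord(
        subject_id=rec.subject_id, trial_id=rec.trial_id, task=rec.task,
        fs_hz=fs_new, channel_names=list(rec.channel_names), samples=x,
        triggers=rec.triggers,
    )
    region_map = region_map or RegionMap()
    if set(region_map.all_channels) <= set(out.channel_names):
        out = average_regions(out, region_map)
    return out
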