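"""On-disk study format: one TSV per trial/subject plus a key-value sidecar.

Signal files carry a header row of channel names and one row per sample;
the sidecar stores sampling rate, triggers and labels. The format is plain
text and round-trips losslessly at the written precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecError
from .synthetic import SignalRecord

_FLOAT_FMT = "%.10g"


def _basename(record: SignalRecord) -> str:
    return f"{record.trial_id}_{record.subject_id}"


def write_study(records: list[SignalRecord], directory: str | Path) -> list[Path]:
    """Write each record as ``<trial>_<subject>.tsv`` + ``.meta`` sidecar."""
    if not records:
        raise InvalidSpecError("cannot write an empty study")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rec in records:
        base = directory / _basename(rec)
        sig_path = base.with_suffix(".tsv")
        df = pd.DataFrame(rec.samples.T, columns=rec.channel_names)
        df.to_csv(sig_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        meta_path = base.with_suffix(".meta")
        t1, t2, t3 = rec.triggers
        meta_path.write_text(
            f"subject_id: {rec.subject_id}\n"
            f"trial_id: {rec.trial_id}\n"
            f"task: {rec.task}\n"
            f"fs_hz: {rec.fs_hz!r}\n"
            f"triggers: {t1!r}, {t2!r}, {t3!r}\n"
        )
        written.extend([sig_path, meta_path])
    return written


def _read_meta(path: Path) -> dict[str, str]:
    meta = {}
    for line in path.read_text().splitlines():
        if line.strip():
            key, value = line.split(":", 1)
            meta[key.strip()] = value.strip()
    return meta


def read_record(sig_path: str | Path) -> SignalRecord:
    sig_path = Path(sig_path)
    meta = _read_meta(sig_path.with_suffix(".meta"))
    df = pd.read_csv(sig_path, sep="\t")
    triggers = tuple(float(v) for v in meta["triggers"].split(","))
    return SignalRecord(
        subject_id=meta["subject_id"],
        trial_id=meta["trial_id"],
        task=meta["task"],
        fs_hz=float(meta["fs_hz"]),
        channel_names=list(df.columns),
        samples=df.to_numpy().T,
        triggers=triggers,  # type: ignore[arg-type]
    )


def read_study(directory: str | Path) -> list[SignalRecord]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv signal files under {directory}")
    return [read_record(p) for p in paths]


# --------------------------------------------------------------------------
# coherence grid (long-format delimited text)


def write_coherence_grid(cmap, path: str | Path) -> Path:
    """Write a CoherenceMap as long-format TSV: time, frequency, coherence,
    significance flag (when the mask is filled)."""
    path = Path(path)
    nf, nt = cmap.coh.shape
    df = pd.DataFrame(
        {
            "time_s": np.tile(cmap.times, nf),
            "freq_hz": np.repeat(cmap.freqs, nt),
            "coherence": cmap.coh.ravel(),
            "significant": (
                cmap.sig_mask.ravel().astype(int) if cmap.sig_mask is not None
                else np.full(nf * nt, -1)
            ),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_coherence_grid(path: str | Path):
    """Read a grid written by :func:`write_coherence_grid`."""
    from .coherence import CoherenceMap

    df = pd.read_csv(path, sep="\t")
    freqs = np.unique(df["freq_hz"].to_numpy())
    times = np.unique(df["time_s"].to_numpy())
    nf, nt = freqs.size, times.size
    order = np.lexsort((df["time_s"].to_numpy(), df["freq_hz"].to_numpy()))
    coh = df["coherence"].to_numpy()[order].reshape(nf, nt)
    sig = df["significant"].to_numpy()[order].reshape(nf, nt)
    mask = None if (sig < 0).all() else sig > 0
    return CoherenceMap(times=times, freqs=freqs, coh=coh, sig_mask=mask)
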