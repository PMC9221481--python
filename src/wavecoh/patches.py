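"""Significant-patch extraction and the Sum5PaD / WFreq summary statistics.

A patch is a 4-connected component of the pointwise significance mask.
Sum5PaD (%) is the summed duration of the five longest patches whose
frequency extent intersects a band (default 8-15 Hz, where the mechanical
muscle rhythm lives), relative to the whole trial duration; overlapping
patches at different frequencies make values above 100 % legal. WFreq (Hz)
is the duration-weighted mean of those patches' representative frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigError
from .coherence import CoherenceMap

#: default summary bands: the muscle-rhythm band and the wide band
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((8.0, 15.0), (3.0, 25.0))

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class Patch:
    """One connected significant region of the time-frequency plane.

    ``t_min``/``t_max`` are the left edge of the first and the right edge of
    the last member pixel, so ``duration = t_max - t_min`` is always positive.
    ``weighted_freq`` is the coherence-weighted mean frequency over member
    pixels (the patch's representative frequency for WFreq).
    """

    id: int
    t_min: float
    t_max: float
    duration: float
    f_min: float
    f_max: float
    f_range: float
    mean_coh: float
    weighted_freq: float
    pixels: np.ndarray | None = field(default=None, compare=False, repr=False)

    @property
    def midpoint_freq(self) -> float:
        return 0.5 * (self.f_min + self.f_max)

    def intersects_band(self, band: tuple[float, float]) -> bool:
        return self.f_max >= band[0] and self.f_min <= band[1]


@dataclass
class PatchSummary:
    """Per-band summary of one coherence map (one signal pair, one trial)."""

    band: tuple[float, float]
    sum5pad_pct: float
    wfreq_hz: float | None  # None when no in-band patch exists
    n_patches: int
    total_duration_s: float


def extract_patches(cmap: CoherenceMap, connectivity: int = 4) -> list[Patch]:
    """Connected components of the significance mask, sorted by duration
    (descending; ties broken by earlier start)."""
    if cmap.sig_mask is None:
        raise ConfigError("significance mask not filled; run pointwise_significance first")
    structure = {4: _FOUR_CONN, 8: _EIGHT_CONN}.get(connectivity)
    if structure is None:
        raise ConfigError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n_labels = ndimage.label(cmap.sig_mask, structure=structure)
    dt = cmap.dt
    patches: list[Patch] = []
    for k, sl in enumerate(ndimage.find_objects(labels), start=1):
        rows, cols = np.nonzero(labels[sl] == k)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        coh_vals = cmap.coh[rows, cols]
        f_vals = cmap.freqs[rows]
        t_min = float(cmap.times[cols.min()])
        # pixel-count based width keeps equal-width patches exactly tied
        width = (int(cols.max()) - int(cols.min()) + 1) * dt
        patches.append(
            Patch(
                id=k,
                t_min=t_min,
                t_max=t_min + width,
                duration=width,
                f_min=float(f_vals.min()),
                f_max=float(f_vals.max()),
                f_range=float(f_vals.max() - f_vals.min()),
                mean_coh=float(coh_vals.mean()),
                weighted_freq=float(np.average(f_vals, weights=coh_vals)),
                pixels=np.column_stack([rows, cols]),
            )
        )
    patches.sort(key=lambda p: (-p.duration, p.t_min))
    for i, p in enumerate(patches, start=1):
        p.id = i
    return patches


def _top5_in_band(patches: list[Patch], band: tuple[float, float]) -> list[Patch]:
    in_band = [p for p in patches if p.intersects_band(band)]
    in_band.sort(key=lambda p: (-p.duration, p.t_min))
    return in_band[:5]


def band_clipped_duration(patch: Patch, cmap: CoherenceMap, band: tuple[float, float]) -> float:
    """Duration counting only time columns with an in-band member pixel."""
    if patch.pixels is None:
        raise ConfigError("band clipping needs pixel membership (re-extract patches)")
    rows, cols = patch.pixels[:, 0], patch.pixels[:, 1]
    in_band = (cmap.freqs[rows] >= band[0]) & (cmap.freqs[rows] <= band[1])
    return float(np.unique(cols[in_band]).size) * cmap.dt


def sum5pad(
    patches: list[Patch],
    band: tuple[float, float],
    total_duration_s: float,
    clip_to_band: bool = False,
    cmap: CoherenceMap | None = None,
) -> float:
    """Summed duration of the five longest in-band patches as % of the whole
    duration. A patch counts if its frequency extent intersects the band and
    by default contributes its full duration, so values > 100 % are legal;
    with ``clip_to_band`` only time columns with in-band pixels count (needs
    the source map)."""
    if total_duration_s <= 0:
        raise ConfigError(f"total_duration_s={total_duration_s} must be positive")
    top = _top5_in_band(patches, band)
    if clip_to_band:
        if cmap is None:
            raise ConfigError("clip_to_band requires the source CoherenceMap")
        return 100.0 * sum(band_clipped_duration(p, cmap, band) for p in top) / total_duration_s
    return 100.0 * sum(p.duration for p in top) / total_duration_s


def wfreq(
    patches: list[Patch], band: tuple[float, float], method: str = "weighted"
) -> float | None:
    """Duration-weighted mean representative frequency of the five longest
    in-band patches; ``None`` when no patch intersects the band.

    ``method='weighted'`` uses each patch's coherence-weighted pixel mean
    frequency (clipped into the band); ``'midpoint'`` uses (f_min+f_max)/2.
    """
    if method not in ("weighted", "midpoint"):
        raise ConfigError(f"unknown WFreq method {method!r}")
    top = _top5_in_band(patches, band)
    if not top:
        return None
    reps = np.array(
        [p.weighted_freq if method == "weighted" else p.midpoint_freq for p in top]
    )
    reps = np.clip(reps, band[0], band[1])
    durations = np.array([p.duration for p in top])
    return float(np.sum(durations * reps) / np.sum(durations))


def summarize(
    cmap: CoherenceMap,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    connectivity: int = 4,
    wfreq_method: str = "weighted",
    clip_to_band: bool = False,
) -> list[PatchSummary]:
    """One PatchSummary per requested band."""
    f_lo, f_hi = float(cmap.freqs.min()), float(cmap.freqs.max())
    for band in bands:
        if band[0] < f_lo - 1e-9 or band[1] > f_hi + 1e-9:
            raise ConfigError(f"band {band} outside the analysed range [{f_lo}, {f_hi}] Hz")
    patches = extract_patches(cmap, connectivity)
    total = cmap.total_duration_s
    out = []
    for band in bands:
        in_band = [p for p in patches if p.intersects_band(band)]
        out.append(
            PatchSummary(
                band=band,
                sum5pad_pct=sum5pad(patches, band, total, clip_to_band, cmap),
                wfreq_hz=wfreq(patches, band, wfreq_method),
                n_patches=len(in_band),
                total_duration_s=total,
            )
        )
    return out


# --------------------------------------------------------------------------
# patch table export (the six documented value groups)

_COLUMNS = [
    "patch_id", "t_min_s", "t_max_s", "duration_s",
    "f_min_hz", "f_max_hz", "f_range_hz", "mean_coh", "weighted_freq_hz",
]


def export_patch_table(cmap: CoherenceMap, patches: list[Patch], path: str | Path) -> Path:
    """Write the per-patch descriptor table (delimited text).

    Header comments carry the whole-series duration and the patch count; the
    columns mirror the documented export: patch times, duration, frequency
    extent and range, plus mean coherence and representative frequency.
    """
    path = Path(path)
    rows = [
        (p.id, p.t_min, p.t_max, p.duration, p.f_min, p.f_max, p.f_range,
         p.mean_coh, p.weighted_freq)
        for p in patches
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# total_duration_s\t{cmap.total_duration_s!r}\n")
        fh.write(f"# n_patches\t{len(patches)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_patch_table(path: str | Path) -> tuple[float, int, list[Patch]]:
    """Read back an exported table -> (total_duration_s, n_patches, patches).

    Pixel membership is not stored, so returned patches carry descriptors only.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, value = line[1:].strip().split("\t")
            meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    patches = [
        Patch(
            id=int(r.patch_id), t_min=r.t_min_s, t_max=r.t_max_s, duration=r.duration_s,
            f_min=r.f_min_hz, f_max=r.f_max_hz, f_range=r.f_range_hz,
            mean_coh=r.mean_coh, weighted_freq=r.weighted_freq_hz,
        )
        for r in df.itertuples()
    ]
    return float(meta["total_duration_s"]), int(meta["n_patches"]), patches
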