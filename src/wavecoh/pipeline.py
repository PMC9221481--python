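"""End-to-end orchestration: simulate -> preprocess -> coherence -> patches
-> compare, with seed propagation and a run manifest.

A run is driven by one flat RunConfig; the global seed deterministically
derives every stochastic stage (trial generation, random pairing, surrogate
tests), so reruns with the same config are bit-identical for all
deterministic outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coherence import WaveletConfig, significant_coherence
from .exceptions import ConfigError, WavecohError
from .pairing import (
    PairSpec, aggregate, build_random_pairs, build_real_pairs, cells_from_units,
    classify_pair, split_signal,
)
from .patches import DEFAULT_BANDS, extract_patches, export_patch_table, summarize
from .plotting import plot_coherence
from .preprocess import PreprocConfig, preprocess_record, truncate_to_common_length
from .stats import compare_real_vs_random, compare_tasks
from .studyio import write_study
from .synthetic import SignalRecord, TrialSpec, make_study

logger = logging.getLogger(__name__)

#: region combinations analysed by default; the full 378-pair set is
#: available by setting combos=None, at a proportional runtime cost
DEFAULT_COMBOS: tuple[str, ...] = ("intra-MMGs", "inter-MMGs", "inter-MMGs-EEGcen")


@dataclass
class RunConfig:
    trial: TrialSpec = field(default_factory=TrialSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    n_trials: int = 6
    combos: tuple[str, ...] | None = DEFAULT_COMBOS
    designs: tuple[str, ...] = ("real-vs-random",)
    out_dir: str = "wavecoh_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.trial.validate()
        self.wavelet.validate()
        for band in self.bands:
            if band[0] < self.wavelet.f_min or band[1] > self.wavelet.f_max:
                raise ConfigError(
                    f"band {list(band)} outside analysed range "
                    f"[{self.wavelet.f_min}, {self.wavelet.f_max}] Hz "
                    f"(f_max={self.wavelet.f_max} bound)"
                )
        for design in self.designs:
            if design not in ("real-vs-random", "hima-vs-pima"):
                raise ConfigError(f"unknown pipeline design {design!r}")


def _signal_bank(records: list[SignalRecord]) -> dict[str, dict[str, np.ndarray]]:
    """trial_id -> signal name -> samples (shared sensors taken once)."""
    bank: dict[str, dict[str, np.ndarray]] = {}
    for rec in records:
        trial = bank.setdefault(rec.trial_id, {})
        for ch in rec.channel_names:
            name = ch if ch in ("force", "ACC") else f"{rec.subject_id}:{ch}"
            trial[name] = rec.channel(ch)
    return bank


def _trial_meta(records: list[SignalRecord]) -> dict[str, dict[str, str]]:
    meta: dict[str, dict[str, str]] = {}
    for rec in records:
        meta.setdefault(rec.trial_id, {})[rec.subject_id] = rec.task
    for trial, tasks in meta.items():
        tasks["configuration"] = "_".join(f"{s}-{t}" for s, t in sorted(tasks.items()))
    return meta


def _pair_values(
    specs: list[PairSpec],
    bank: dict[str, dict[str, np.ndarray]],
    meta: dict[str, dict[str, str]],
    fs: float,
    config: WaveletConfig,
    bands,
    rng: np.random.Generator,
    combos: tuple[str, ...] | None,
) -> pd.DataFrame:
    rows = []
    for spec in specs:
        combo = classify_pair(spec.side_a, spec.side_b)[1]
        if combos is not None and combo not in combos:
            continue
        x = bank[spec.trial_a][spec.side_a]
        y = bank[spec.trial_b][spec.side_b]
        n = min(x.size, y.size)
        cmap = significant_coherence(x[:n], y[:n], fs, config, rng=rng)
        subj_a = split_signal(spec.side_a)[0]
        subj_b = split_signal(spec.side_b)[0]
        for summary in summarize(cmap, bands):
            lo, hi = summary.band
            for pname, value in (
                (f"Sum5PaD_{lo:g}-{hi:g}Hz", summary.sum5pad_pct),
                (f"WFreq_{lo:g}-{hi:g}Hz", summary.wfreq_hz),
            ):
                rows.append(
                    dict(
                        signal_a=spec.side_a, signal_b=spec.side_b,
                        trial_id=spec.trial_a if spec.pairing == "real" else
                        f"{spec.trial_a}|{spec.trial_b}",
                        configuration=meta[spec.trial_a]["configuration"],
                        task_a=meta[spec.trial_a].get(subj_a, ""),
                        task_b=meta[spec.trial_b].get(subj_b, ""),
                        parameter=pname,
                        value=np.nan if value is None else value,
                    )
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    stage = "simulate"
    try:
        trial_seed = int(seeds[0].generate_state(1)[0] % 2**31)
        spec = replace(config.trial, seed=trial_seed)
        records = make_study(spec, config.n_trials)
        files += [str(p) for p in write_study(records, out / "signals")]
        logger.info("simulated %d trials x 2 subjects, %.1f s at %g Hz",
                    config.n_trials, spec.duration_s, spec.fs_hz)

        stage = "preprocess"
        processed = [preprocess_record(r, config.preproc) for r in records]
        processed = truncate_to_common_length(processed)
        fs = processed[0].fs_hz
        logger.info("preprocessed to %g Hz, common length %d samples",
                    fs, processed[0].n_samples)

        stage = "coherence"
        bank = _signal_bank(processed)
        meta = _trial_meta(processed)
        trial_ids = sorted(bank)
        wav = replace(config.wavelet,
                      seed=int(seeds[1].generate_state(1)[0] % 2**31))
        rng = np.random.default_rng(wav.seed)
        real_specs = build_real_pairs(trial_ids)
        random_specs = build_random_pairs(trial_ids, rng)
        real_values = _pair_values(real_specs, bank, meta, fs, wav, config.bands,
                                   rng, config.combos)
        random_values = _pair_values(random_specs, bank, meta, fs, wav, config.bands,
                                     rng, config.combos)
        for name, df in (("real_values.tsv", real_values),
                         ("random_values.tsv", random_values)):
            p = out / name
            df.to_csv(p, sep="\t", index=False)
            files.append(str(p))

        # illustrative outputs for the first analysed real pair
        if len(real_values):
            first = real_values.iloc[0]
            x = bank[trial_ids[0]][first.signal_a]
            y = bank[trial_ids[0]][first.signal_b]
            cmap = significant_coherence(x, y, fs, wav,
                                         rng=np.random.default_rng(wav.seed))
            patches = extract_patches(cmap)
            p = export_patch_table(cmap, patches, out / "example_patches.tsv")
            files.append(str(p))
            p = plot_coherence(cmap, patches, out / "example_coherence.png",
                               title=f"{first.signal_a} vs {first.signal_b}")
            files.append(str(p))

        stage = "compare"
        for design in config.designs:
            if design == "real-vs-random":
                for scope in ("intrapersonal", "interpersonal", "force_acc"):
                    cells_r = cells_from_units(aggregate(real_values, scope))
                    cells_s = cells_from_units(aggregate(random_values, scope))
                    if not cells_r:
                        continue
                    table = compare_real_vs_random(cells_r, cells_s)
                    p = out / f"compare_real_vs_random_{scope}.tsv"
                    table.to_csv(p, sep="\t", index=False)
                    files.append(str(p))
            else:  # hima-vs-pima
                units = aggregate(real_values, "task_grouped")
                table = compare_tasks(units)
                p = out / "compare_hima_vs_pima.tsv"
                table.to_csv(p, sep="\t", index=False)
                files.append(str(p))
    except WavecohError as err:
        raise WavecohError(f"stage {stage!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "n_trials": config.n_trials,
        "files": sorted(files),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
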