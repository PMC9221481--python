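"""Signal-pair construction and the aggregation tree for the coherence
parameters.

Signals are addressed as ``"<subject>:<channel>"`` (e.g. ``"A:MMGtri"``,
``"B:TLri"``) or as the shared single-sensor channels ``"force"`` and
``"ACC"``. The canonical two-subject layout has 28 signals (2 shared + 2x3
muscle + 2x10 EEG sub-regions), giving C(28, 2) = 378 unordered pairs.

Real pairs take both sides from the same trial; random pairs take the two
sides from different trials, which destroys any genuine interaction while
keeping single-signal structure — the coincidence null of the study design.

Aggregation: the unit entering the group statistics is the unordered
signal-TYPE pair within a region combination. Values are averaged over the
trials of each task configuration, then over configurations, and over the
two subject/direction assignments — except for force/ACC combinations,
where the two partners are pooled as separate units (not averaged) to keep
workable sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import PairingError
from .preprocess import DEFAULT_REGION_OF
from .synthetic import EEG_CHANNELS, MMG_CHANNELS, SHARED_CHANNELS

_FAMILY_ORDER = ("MMGs", "EEGcen", "EEGle", "EEGri")


@dataclass(frozen=True)
class PairSpec:
    """One signal pair to analyse: sides, pairing mode and trial sources."""

    side_a: str
    side_b: str
    pairing: str  # "real" | "random"
    trial_a: str
    trial_b: str
    scope: str  # "intrapersonal" | "interpersonal" | "force_acc"

    def __post_init__(self) -> None:
        if self.side_a == self.side_b:
            raise PairingError(f"pair of a signal with itself: {self.side_a}")
        if self.pairing == "real" and self.trial_a != self.trial_b:
            raise PairingError("real pairs must come from one trial")
        if self.pairing == "random" and self.trial_a == self.trial_b:
            raise PairingError("random pairs must come from different trials")


def signal_layout(subjects: tuple[str, str] = ("A", "B")) -> list[str]:
    """The 28 canonical signal names of a two-subject trial."""
    names = list(SHARED_CHANNELS)
    for s in subjects:
        names.extend(f"{s}:{ch}" for ch in MMG_CHANNELS)
    for s in subjects:
        names.extend(f"{s}:{ch}" for ch in EEG_CHANNELS)
    return names


def split_signal(name: str) -> tuple[str | None, str]:
    """-> (subject or None for shared sensors, channel)."""
    if ":" in name:
        subject, channel = name.split(":", 1)
        return subject, channel
    return None, name


def family_of(channel: str) -> str:
    """Channel -> statistics family: MMGs, EEGcen/le/ri, force, ACC."""
    if channel in MMG_CHANNELS:
        return "MMGs"
    if channel in DEFAULT_REGION_OF:
        return DEFAULT_REGION_OF[channel]
    if channel in SHARED_CHANNELS:
        return channel
    return "other"  # custom layouts outside the canonical 28-signal design


def classify_pair(sig_a: str, sig_b: str) -> tuple[str, str, tuple[str, ...]]:
    """-> (scope, region_combo label, aggregation unit key).

    The unit key identifies the signal-type pair independently of subject
    and direction; for force/ACC combos it additionally carries the partner,
    because partners are pooled rather than averaged there.
    """
    subj_a, ch_a = split_signal(sig_a)
    subj_b, ch_b = split_signal(sig_b)
    fam_a, fam_b = family_of(ch_a), family_of(ch_b)
    if subj_a is None or subj_b is None:
        if subj_a is None and subj_b is None:  # force vs ACC
            return "force_acc", "force-ACC", tuple(sorted((ch_a, ch_b)))
        shared, partner_subj, partner_ch, partner_fam = (
            (ch_a, subj_b, ch_b, fam_b) if subj_a is None else (ch_b, subj_a, ch_a, fam_a)
        )
        combo = f"{shared}-{partner_fam}"
        return "force_acc", combo, (shared, partner_ch, partner_subj)
    fams = sorted(
        {fam_a, fam_b},
        key=lambda f: (_FAMILY_ORDER.index(f) if f in _FAMILY_ORDER else len(_FAMILY_ORDER), f),
    )
    scope = "intrapersonal" if subj_a == subj_b else "interpersonal"
    prefix = "intra" if scope == "intrapersonal" else "inter"
    combo = f"{prefix}-{'-'.join(fams)}"
    return scope, combo, tuple(sorted((ch_a, ch_b)))


def enumerate_signal_pairs(signal_names: list[str] | None = None) -> list[tuple[str, str]]:
    """All unordered pairs of distinct signals (378 for the default layout)."""
    if signal_names is None:
        signal_names = signal_layout()
    if len(set(signal_names)) != len(signal_names):
        raise PairingError("duplicate signal names")
    return list(combinations(signal_names, 2))


def build_real_pairs(trial_ids: list[str], signal_names: list[str] | None = None) -> list[PairSpec]:
    """One real PairSpec per signal pair per trial."""
    pairs = enumerate_signal_pairs(signal_names)
    return [
        PairSpec(a, b, "real", t, t, classify_pair(a, b)[0])
        for t in trial_ids
        for a, b in pairs
    ]


def build_random_pairs(
    trial_ids: list[str],
    seed: int | np.random.Generator = 0,
    signal_names: list[str] | None = None,
    n_per_pair: int = 1,
) -> list[PairSpec]:
    """For every signal-pair type, ``n_per_pair`` random PairSpecs whose two
    sides come from different trials (chosen uniformly under the seed)."""
    if len(trial_ids) < 2:
        raise PairingError("random pairing needs at least two trials")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = enumerate_signal_pairs(signal_names)
    specs = []
    for a, b in pairs:
        for _ in range(n_per_pair):
            ia, ib = rng.choice(len(trial_ids), size=2, replace=False)
            specs.append(
                PairSpec(a, b, "random", trial_ids[ia], trial_ids[ib], classify_pair(a, b)[0])
            )
    return specs


# --------------------------------------------------------------------------
# aggregation


def aggregate(values: pd.DataFrame, design: str) -> pd.DataFrame:
    """Aggregate per-pair per-trial parameter values into unit-level means.

    ``values`` needs columns: signal_a, signal_b, trial_id, configuration,
    parameter, value — and, for ``design='task_grouped'``, task_a and task_b
    (the task of each side's subject in that trial). Returns one row per
    (region_combo, parameter, unit) — plus task for the task-grouped design —
    with the staged mean described in the module docstring. Missing values
    propagate as NaN.

    designs: intrapersonal | interpersonal | force_acc | task_grouped
    """
    if design not in ("intrapersonal", "interpersonal", "force_acc", "task_grouped"):
        raise PairingError(f"unknown design {design!r}")
    df = values.copy()
    classified = [classify_pair(a, b) for a, b in zip(df["signal_a"], df["signal_b"])]
    df["scope"] = [c[0] for c in classified]
    df["region_combo"] = [c[1] for c in classified]
    df["unit"] = ["|".join(c[2]) for c in classified]

    if design == "task_grouped":
        frames = []
        for side in ("a", "b"):
            subjects = [split_signal(s)[0] for s in df[f"signal_{side}"]]
            sub = df.assign(partner=subjects, task=df[f"task_{side}"])
            frames.append(sub[sub["partner"].notna()])
        long = pd.concat(frames, ignore_index=True).drop_duplicates(
            subset=["region_combo", "parameter", "unit", "trial_id", "partner", "task",
                    "signal_a", "signal_b"]
        )
        out = (
            long.groupby(["region_combo", "parameter", "unit", "partner", "task"])["value"]
            .mean()
            .reset_index()
        )
        return out

    df = df[df["scope"] == design]
    if df.empty:
        return pd.DataFrame(columns=["region_combo", "parameter", "unit", "value"])
    if design == "intrapersonal":
        subjects = [split_signal(a)[0] for a in df["signal_a"]]
        df = df.assign(subject=subjects)
        # trials -> per (subject, configuration); then configurations; then subjects
        step = df.groupby(
            ["region_combo", "parameter", "unit", "subject", "configuration"]
        )["value"].mean()
        step = step.groupby(["region_combo", "parameter", "unit", "subject"]).mean()
        out = step.groupby(["region_combo", "parameter", "unit"]).mean()
    elif design == "interpersonal":
        # trials and direction assignments -> per configuration; then configurations
        step = df.groupby(["region_combo", "parameter", "unit", "configuration"])["value"].mean()
        out = step.groupby(["region_combo", "parameter", "unit"]).mean()
    else:  # force_acc: unit already carries the partner; pool, don't average
        step = df.groupby(["region_combo", "parameter", "unit", "configuration"])["value"].mean()
        out = step.groupby(["region_combo", "parameter", "unit"]).mean()
    return out.reset_index()


@dataclass
class ComparisonCell:
    """Aggregated values of one region combination and parameter."""

    region_combo: str
    parameter: str
    values: np.ndarray
    n: int
    mean: float
    sd: float
    cv: float | None

    @classmethod
    def from_values(cls, region_combo: str, parameter: str, values: np.ndarray) -> "ComparisonCell":
        from .stats import coefficient_of_variation

        values = np.asarray(values, dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return cls(
            region_combo=region_combo, parameter=parameter, values=values,
            n=values.size, mean=mean, sd=sd,
            cv=coefficient_of_variation(values) if values.size > 1 else None,
        )


def cells_from_units(units: pd.DataFrame) -> list[ComparisonCell]:
    """Group unit-level aggregates into one ComparisonCell per combo/parameter."""
    return [
        ComparisonCell.from_values(combo, parameter, sub["value"].to_numpy())
        for (combo, parameter), sub in units.groupby(["region_combo", "parameter"])
    ]
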