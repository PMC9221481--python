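# wavecoh

Wavelet coherence analysis of paired physiological time series — muscle
(MMG/MTG), brain (EEG sub-regions) and shared force/acceleration channels
recorded from two persons performing a coupled isometric task
(hyperscanning-style designs). The package is for researchers who want to
quantify when and at which frequencies two such signals oscillate
coherently, decide which of those patches are statistically meaningful,
and compare genuinely interacting ("real") signal pairs against a
coincidence null of randomly re-paired trials.

## What it computes

For two series *s_x*, *s_y* the package estimates the Morlet wavelet
coherence

    Coh(b, a) = |⟨W_x W_y*⟩| / √(⟨|W_x|²⟩ ⟨|W_y|²⟩) ∈ [0, 1],

with `W s(b, a) = (1/a) ∫ g*((t−b)/a) s(t) dt` and the Morlet mother
wavelet `g_σ(x) = e^{ix} e^{−x²/(2σ²)}`, on a log-spaced 3–30 Hz grid.
Pointwise significance comes from phase-randomised surrogate pairs: per
frequency, the empirical 95 % quantile of surrogate coherence is the
threshold (α = 0.05). Connected significant regions ("patches") are then
summarised per band by

- **Sum5PaD (%)** — summed duration of the five longest patches in the
  band (default 8–15 Hz, the mechanical muscle rhythm) relative to trial
  duration (can exceed 100 % when patches overlap in time), and
- **WFreq (Hz)** — their duration-weighted mean frequency.

The statistics layer aggregates these over trials and region combinations
and compares real vs randomly matched pairs (paired t / Wilcoxon with
Cohen's d_z = |t|/√n or r = |z|/√n, Shapiro–Wilk routing) and holding vs
pushing tasks (repeated-measures ANOVA with Greenhouse–Geisser
correction). A synthetic-data module generates coupled two-subject
studies with configurable coupling strength so the whole chain is testable
without any recordings. See `docs/methods.md` for the full model.

## Worked example

```python
import numpy as np
from wavecoh import (TrialSpec, make_trial_pair, WaveletConfig,
                     significant_coherence, extract_patches, summarize)

spec = TrialSpec(duration_s=12.0, fs_hz=250.0, coupling=0.9, seed=21)
rec_a, rec_b = make_trial_pair(spec)
cmap = significant_coherence(rec_a.channel("MMGtri"), rec_b.channel("MMGtri"),
                             fs=250.0, config=WaveletConfig(n_surrogates=100, seed=3))
for s in summarize(cmap):
    print(f"band {s.band[0]:g}-{s.band[1]:g} Hz: {s.n_patches} patches, "
          f"Sum5PaD {s.sum5pad_pct:.1f} %, WFreq {s.wfreq_hz:.2f} Hz")
```

prints

```
band 8-15 Hz: 1 patches, Sum5PaD 100.0 %, WFreq 9.69 Hz
band 3-25 Hz: 6 patches, Sum5PaD 116.5 %, WFreq 9.42 Hz
```

With coupling 0.9 the two muscle channels share a phase-jittered ~10 Hz
drive, so a single significant patch covers the whole trial in the 8–15 Hz
band (Sum5PaD 100 %; in the wide band the top-five patches overlap in time
at different frequencies, pushing the sum above 100 %), and the weighted
frequency sits at the drive frequency. Re-running with `coupling=0`
collapses Sum5PaD to near-chance values.

The same analysis is scriptable from the shell:

```bash
wavecoh simulate --duration-s 12 --coupling 0.9 --n-trials 2 --out-dir raw/
wavecoh preprocess --in-dir raw/ --out-dir proc/ --truncate
wavecoh coherence --in-dir proc/ --signal-a A:MMGtri --signal-b B:MMGtri \
        --trial trial1 --out-prefix coh1
wavecoh patches --grid coh1.tsv --out patches1.tsv
wavecoh run --out-dir full_run --seed 7    # whole pipeline + comparison tables
```

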