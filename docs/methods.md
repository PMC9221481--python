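# Methods

`wavecoh` analyses the time-resolved coupling of paired physiological
recordings — mechanical muscle oscillations (MMG/MTG), EEG sub-region
averages, and shared force/acceleration sensors — from two persons
performing a coupled isometric task. This note documents the model and the
estimator choices, what the synthetic generator does and does not emulate,
and the numerical decisions a user may want to revisit.

## Signal model and preprocessing

Recordings arrive as multichannel trials at 1 kHz with three triggers
(start of measurement, start and end of the isometric force plateau). The
conditioning chain is fixed:

1. **Trial cutting.** Task trials are cut to the plateau `[t2, t3]`.
   Maximal-contraction (MVIC) trials shorter than 3 s are extended backwards
   to the force increase so that at least 3 s remain (3 s is the minimum the
   wavelet analysis needs at 3 Hz); resting trials are used whole.
2. **Notch 49–51 Hz.** Power-line removal, implemented as a second-order
   IIR notch at 50 Hz with 2 Hz bandwidth, applied forward–backward.
3. **Bandpass 0.016–256 Hz.** The default is a 25-tap windowed-sinc FIR
   (Hamming window), applied zero-phase at the original 1 kHz rate (the
   256 Hz edge requires the original rate). A 25-tap kernel cannot realise
   the 0.016 Hz edge — its DC gain is ≈ 1 — so this stage shapes only the
   upper band; zero-mean output is the job of the drift stage below. An
   IIR Butterworth bandpass (`bandpass_method="butter"`) is available and
   does null DC.
4. **Decimation 1000 → 250 Hz** after a zero-phase FIR anti-alias lowpass
   at 100 Hz (comfortably below the new Nyquist of 125 Hz while preserving
   everything the 3–30 Hz analysis uses).
5. **Drift removal.** The signal minus its order-10 Butterworth 1 Hz
   lowpass, applied zero-phase with extended reflection padding (3 s at the
   1 Hz cutoff) to keep edge transients below a few percent. This pulls
   every trace down to oscillate around zero, which the wavelet estimator
   needs to avoid leakage.
6. **Region averaging.** The 63 scalp electrodes (the reference CPz is
   excluded) are averaged sample-wise into ten sub-regions (FM, C, CP, POc,
   AFle, TLle, POle, AFri, TLri, POri), which group into three statistics
   regions EEGcen / EEGle / EEGri.

All filters are linear and zero-phase, so the stages commute with the
region average and map zero to zero; phase handling is a package decision
(forward–backward filtering), chosen to keep cross-signal phase relations —
the quantity coherence measures — untouched.

## Wavelet coherence

The mother wavelet is the Morlet `g_σ(x) = e^{ix} e^{−x²/(2σ²)}` with
σ = 6 (a standard trade-off giving roughly two-cycle time resolution near
10 Hz; configurable). The transform uses the `1/a` normalisation

    W(b, a) = (1/a) ∫ g*((t − b)/a) s(t) dt,

evaluated by FFT convolution, with scales mapped to frequencies via
f = 1/(2πa) (the σ-dependent correction is < 1 % at σ = 6 and is omitted).
The grid is log-spaced at 12 voices per octave from 3 to 30 Hz (41 rows).

Coherence is the smoothed-cross-spectrum magnitude

    Coh(b, a) = |⟨W_x W_y*⟩| / sqrt(⟨|W_x|²⟩ ⟨|W_y|²⟩) ∈ [0, 1],

where ⟨·⟩ is a boxcar running mean in time whose length grows with scale.
Without smoothing the estimator is identically 1; its length is the
bias/variance knob. The window is parameterised in multiples of the
wavelet duration σ·a (the transform's own correlation length at that
scale), default `smoothing_width = 12`, i.e. ≈ 1.15 s at 10 Hz. The default
was chosen so that the coherence of independent white noise averages ≈ 0.4
— enough variance reduction to separate genuine coupling from the null, in
line with common wavelet-coherence practice — while keeping sub-second
time resolution at the analysis band. No cross-scale smoothing is applied.
No cone-of-influence masking is applied by default (maps are full
rectangles); the FFT evaluation is circular, so the outermost ~2σa of each
row mixes the two signal ends.

**Pointwise significance.** For each signal pair, `n_surrogates = 100`
surrogate pairs are built by independent phase randomisation of each input
(amplitude spectra preserved, all cross-phase structure destroyed; an
i.i.d. white-noise null is available as an option). Coherence is computed
for every surrogate pair, and per frequency row the empirical (1 − α)
quantile of the pooled surrogate values (α = 0.05) is the threshold;
observed pixels strictly above it are flagged. The threshold is per-scale
because the null distribution varies with the smoothing length. The
surrogate loop runs in single precision; the Monte-Carlo error of a
100-surrogate quantile dwarfs float32 rounding. With fewer than 19
surrogates the 5 % quantile is not estimable and the configuration is
rejected. Calibration is verified in the acceptance suite: on independent
white noise the flagged fraction averages 5 % ± 2 pp over 200 replicate
pairs.

## Patch statistics

Significant patches are 4-connected components of the significance mask
(8-connectivity is available; 4 is the conservative choice that separates
diagonally touching blobs). Each patch carries its time extent (left edge
of the first to right edge of the last member pixel, so duration is always
positive), frequency extent and range, mean coherence, and a
representative frequency.

- **Sum5PaD (%)**: the summed duration of the five longest patches whose
  frequency extent intersects the band (default 8–15 Hz, where the ~10 Hz
  muscle rhythm lives), relative to the whole trial duration. A patch that
  straddles the band edge counts with its full duration (an option clips
  instead); overlapping patches at different frequencies can push the value
  above 100 %, which is legal and expected for strongly coupled pairs.
  Fewer than five patches contribute whatever exists.
- **WFreq (Hz)**: the duration-weighted mean of those patches'
  representative frequencies. The representative frequency of a patch is
  its coherence-weighted mean pixel frequency, clipped into the band; the
  patch midpoint (f_min + f_max)/2 is available as an alternative. The
  duration-weighting is fixed; the per-patch representative is the open
  choice, and both options are exposed because neither is canonical.
- Ties among equal-duration patches are broken by earlier start time, so
  the "five longest" selection is deterministic.

A second band, 3–25 Hz, is summarised alongside by default.

## Pairing and aggregation

A two-subject trial yields 28 signals (force, ACC, 2×3 muscle channels,
2×10 EEG sub-regions) and C(28,2) = 378 unordered pairs. *Real* pairs take
both sides from the same trial; *random* pairs draw the two sides from
different trials (uniformly, seeded, without replacement within a draw) —
the coincidence null: any coherence they show cannot come from the
interaction. Random re-pairing requires equal lengths, so records are
truncated to the shortest trial first.

The unit entering the group statistics is the unordered signal-*type* pair
within a region combination. Values are averaged over the trials of each
task configuration, then across configurations, then across the two
subjects (intrapersonal) or direction assignments (interpersonal). This
reproduces the characteristic per-combo sample sizes of the design
(3/6/9/10/12): e.g. three intrapersonal muscle-pair types, 4 + C(4,2) = 10
interpersonal central-EEG types. Force/ACC combinations pool the two
partners as separate units instead of averaging them, to keep workable
sample sizes. Task-grouped aggregation (HIMA vs PIMA) assigns each
partner's trial means to that partner's task in that trial; for
interpersonal combinations the grouping is anchored at the side whose
regions define the combination (directional grouping, switchable).

## Statistics

Normality of the paired differences is checked by Shapiro–Wilk (α = 0.05):
parametric data go to the paired t-test with Cohen's
d_z = |MD|/SD_MD (≡ |t|/√n), non-parametric data to the Wilcoxon
signed-rank test with r = |z|/√n, where z comes from the tie-corrected
normal approximation (exact p for tie-free n ≤ 25; zero differences are
dropped). The coefficient of variation is SD/M. All tests are two-tailed.
Task comparisons with three conditions (HIMA, PIMA, MVIC) use a one-way
repeated-measures ANOVA (via pingouin) with the Greenhouse–Geisser
correction when Mauchly's test rejects sphericity, and partial eta squared
SS_effect/(SS_effect + SS_error) as effect size — the quantity SPSS
reports as "eta squared" for this design. No multiple-testing correction
is applied by default, matching the exploratory design; Benjamini–Hochberg
is available. Report tables round to 3 decimals.

## Synthetic data

No public recordings exist for this design, so the generator produces the
statistical structure the estimators assume:

- a shared drive: a unit-variance ~10 Hz oscillation with random-walk phase
  jitter (default SD 0.05 rad/step at 1 kHz) and a uniform random initial
  phase — independently generated oscillators must not share a phase
  reference;
- muscle channels: `√coupling · shared + √(1 − coupling) · own + noise`,
  where `own` is a subject-private oscillator of the same kind (uncoupled
  subjects still oscillate near 10 Hz, just independently) and the noise
  level is set by an SNR of 6 dB. The square-root amplitude weights make
  the coupling coefficient the *fraction of rhythm variance* contributed by
  the shared drive, so it is directly identifiable from coherence across
  the whole [0, 1] range;
- EEG-like channels: 1/f background (exponent 1) plus a band-limited
  alpha rhythm (8–15 Hz, amplitude 0.5) plus the `√coupling`-weighted
  shared drive at 0 dB gain;
- force/ACC: the shared drive plus sensor noise, written identically into
  both partners' records because one physical sensor serves both;
- triggers at 0 %, 5 % and 95 % of the trial; six fatiguing trials with the
  pushing/holding roles alternating between partners.

Defaults (30 s trials, 1 kHz, coupling 0.8) produce coherence maps with
large sustained patches near 10 Hz for coupled muscle pairs and
near-chance patches for random pairs — the qualitative regime of real
coupled recordings. The generator does **not** emulate fatigue dynamics,
force-level effects, biomechanics, electromyographic content, or
artifacts (eye blinks, cable motion); passing tests therefore demonstrate
that the estimator chain recovers known coupling structure under the
assumed signal model, not that it is robust to every property of real
recordings.

## Problem sizes in the shipped studies

The calibration study uses 200 independent white-noise pairs of 30 s at
250 Hz with 100 surrogates each. The coupling-recovery study sweeps
coupling {0, 0.3, 0.6, 0.9} with 20 ensemble seeds, 20 s trials generated
directly at 250 Hz (the sweep exercises the estimator chain, not the
resampling stages), and 50 surrogates. The orchestrated pipeline defaults
to the muscle-centred region combinations; the full 378-pair analysis is
available by setting `combos=None` at a proportional runtime cost.

## Known limitations

- The smoothing kernel and surrogate construction are estimator choices,
  exposed in configuration rather than fixed as ground truth; absolute
  Sum5PaD values depend on them (the real-vs-random *contrast* is far less
  sensitive).
- Coherence bias near the map edges is not masked by default (no cone of
  influence) and the FFT evaluation is circular.
- The significance test is pointwise: neighbouring pixels are strongly
  correlated, so patch sizes are not themselves corrected for multiplicity
  — exactly why the real-vs-random contrast, not patch existence, carries
  the inference.
- Aggregation assumes the balanced six-trial two-configuration design;
  missing cells propagate as NaN rather than being imputed.
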