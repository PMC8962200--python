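# Methods

## The analysis

`fatiguersp` implements a channel-level spectral analysis of EEG recorded
during a prolonged intermittent motor task: repeated ~5 s submaximal
contractions separated by 2 s rest, performed until self-perceived
exhaustion, recorded at 250 Hz with "Start"/"End" markers at task onset and
offset. Because fatigue grows monotonically over such a session, the
session's trials are split into chronological thirds labelled MinFatg,
ModFatg and SevFatg (minimum / moderate / severe fatigue), and only the
first, middle and last 10 % of trials of the respective thirds are
analysed, so the three groups are maximally separated in time.

### Preprocessing

1. **Band-pass** 1–100 Hz, zero-phase Hamming-windowed sinc FIR
   (`mne.filter.filter_data`). The low-side transition band is set to
   0.6 Hz so sub-hertz drift sits in the stop band rather than halfway
   down the default transition slope.
2. **Notch** at 60 Hz and harmonics below the high cut-off, as narrow FIR
   band-stops of width ±1 Hz.
3. **Common average reference** over the full montage. CAR and the FIR
   filters are linear and commute, so the implementation re-references
   first and then filters only the channels being analysed.
4. **Epoching**, half-open windows, 0-based sample indices,
   `n = round(duration × rate)`:
   - onset epochs span [−1.5, 5.0) s around "Start" (1625 samples at
     250 Hz);
   - offset epochs span [−4.0, 2.0) s around "End"; within each offset
     epoch the span [−4.0, −2.5) s is replaced by that trial's pre-onset
     baseline [−1.5, 0) s, so the baseline read from offset epochs is
     genuine rest rather than mid-contraction signal.
5. **Epoch rejection** by a peak-to-peak amplitude threshold (default
   200 µV on any channel) — an automated stand-in for visual inspection.
   ASR burst correction, ICA decomposition, dipole fitting and IC-level
   (source) analysis are deliberately out of scope; the channel level is
   the implemented surface.
6. **Condition assignment and selection**: retained trials are split into
   thirds of size ⌊T/3⌋ (the trailing T mod 3 trials stay unassigned);
   `n_sel = max(1, round(0.10 × T))` trials are kept per condition — the
   first of MinFatg, the centred block of ModFatg (start offset
   ⌊(set−n_sel)/2⌋), the last of SevFatg. Rounding is half-away-from-zero.
   `fraction = 1` keeps every assigned trial; this special case exists
   because `round(1×T)` would otherwise always exceed the set size.

### ERSP estimator

Per channel and condition, with `S_k(f,t)` the Morlet wavelet coefficient
of trial k:

- mean event-related spectrum `ERS(f,t) = (1/M) Σ_k |S_k(f,t)|²`;
- **common baseline** `B_AVG(f)`: power pooled over the *p* selected
  trials of **all three** conditions and the *q(f)* valid baseline time
  points. Pooling across conditions is essential — baseline power itself
  drifts with fatigue, and a per-condition baseline would absorb the very
  effect under study. (A per-condition baseline remains available through
  `compute_common_baseline` on a condition subset.)
- gain-model ERSP in decibels: `ERSP(f,t) = 10·log10(ERS(f,t)/B_AVG(f))`;
- `ERSP~(f)`: mean over the task-window time points — steady contraction
  [1, 3) s after onset (the force plateau; 0–1 s is the ramp-up), or
  post-contraction [0.25, 1.25) s after offset (0–0.25 s is the ramp-down);
- `ERSP≈`: `ERSP~` further averaged over a band (theta 4–8, alpha 8–13,
  beta 13–30 Hz by default; half-open intervals on the grid);
- `B≈`: the per-condition baseline spectrum expressed against the common
  baseline, `10·log10(B_cond(f)/B_AVG(f))`, band-averaged. The ratio form
  is used throughout; a subtractive log-transform of baseline power is
  dimensionally inconsistent with the dB gain model and is not offered.

Baseline windows: [−1.5, −0.5) s before onset and [−4, −3) s before offset
(the half second nearest the event is excluded as movement anticipation /
residual task activity; the offset-epoch baseline window lies inside the
swapped-in segment).

**Time–frequency decomposition.** Morlet wavelets
(`mne.time_frequency.tfr_array_morlet`) on a linear 3–90 Hz grid at 1 Hz
steps, with cycles `n(f) = 3·(f/3 Hz)^0.5` — few cycles at low
frequencies, growing with the square root of frequency — anchored at 3 Hz
regardless of the grid actually requested, so a restricted grid uses the
same wavelets as the full one. Output times sit on a nominal 50 ms step
snapped to the sample grid. Grid points whose wavelet support
(±5σ_t, σ_t = n/(2πf)) overruns the epoch are marked invalid and excluded
from every average; the counts q and r reflect only valid points.

### Inference

- **Permutation test** over ERSP maps or stacked `ERSP~` spectra: the
  statistic is the one-way repeated-measures ANOVA F at every point (the
  same F as the parametric path); the null permutes the three condition
  labels independently within each subject (sampling without replacement,
  paired design), 2000 permutations by default;
  `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` — the add-one rule forbids
  p = 0 and ties count conservatively against rejection.
- **BH-FDR** (Benjamini–Hochberg step-up, `statsmodels.multipletests`) at
  q = 0.05 across all points of one channel-window analysis; masks are
  never pooled across channels.
- **RM-ANOVA** on the N×3 table of `ERSP≈` values:
  `F = MS_cond / MS_(cond×subject)`, df (2, 2(N−1)), implemented as a
  closed-form sum-of-squares decomposition vectorised across points so the
  permutation engine can reuse it; cross-checked in the tests against
  `statsmodels.AnovaRM` and a brute-force decomposition. No sphericity
  correction is applied by default (plain RM-ANOVA).
- **Bonferroni post-hoc**: paired two-sided t per condition pair,
  adjusted `p = min(1, 3·p_raw)`, computed only when the omnibus p < 0.05
  (reported as `--` otherwise). Zero-variance paired differences give
  p = 0 when the mean difference is non-zero and p = 1 otherwise.

### Classification

12-dimensional per-trial features: single-trial gain-model ERSP (M = 1),
averaged over the task window and band, for six motor channels (FC3, C1,
C3, C5, CP1, CP3) × two bands (alpha, beta). Trials are pooled across
subjects and classified with a linear SVM (C = 1, no tuning) under
stratified 10-fold cross-validation; features are standardised with
training-fold statistics only. Stratification and within-fold
standardisation are adopted to avoid class-imbalance artefacts and
leakage; a subject-grouped CV mode (`grouped=True`) is provided for
leakage-aware evaluation across subjects.

## The synthetic cohort

No public data exist for this protocol, so the generator *is* the study
bed. Defaults are the study conditions: 14 subjects, 60 trials (5 s
contraction + 2 s rest) at 250 Hz, six motor channels plus two unrelated
posterior channels (PO7, PO8).

Each channel carries:

- **1/f background** (exponent 1.0, 5 µV RMS), synthesised as a shaped
  complex-Gaussian spectrum;
- **60 Hz line contamination** (2 µV, random phase per subject);
- **band-limited oscillations**: theta/alpha/beta carriers of Gaussian
  noise (base RMS 3.5 / 9 / 3.5 µV), not pure tones, so time–frequency
  estimates have realistic variance.

**Injected fatigue effect.** In motor channels the carrier amplitude steps
with the trial's chronological third: dB increments (0, +1.5, +3.0) per
condition in every band by default, jittered per subject with SD 1 dB on
the ModFatg/SevFatg conditions (MinFatg is the reference). A linear-drift
profile is available (`effect_profile="linear"`). The effect also applies
during rest at a configurable fraction of its dB value
(`rest_fraction = 0.5`), emulating the observation that resting baseline
power scales with fatigue; the common baseline exists precisely to keep
this drift out of the condition contrasts.

**Calibration.** Within each task segment the carrier is rescaled so its
nominal-band RMS is exactly 1 over that segment's *calibration window* —
the steady interval (1–3 s post-onset) for contractions and the baseline
interval (1.5–0.5 s before the next onset) for rest — before the condition
amplitude is applied. Injected band power is therefore exact in the
windows the analysis reads, rather than a random draw, which is what makes
±0.5 dB recovery checks meaningful at n = 14. The piecewise scale profile
is smoothed with a 0.1 s Hann kernel so segment boundaries introduce no
broadband discontinuity (which would otherwise corrupt the 1/f slope).

**Carrier bandwidth.** Each carrier may extend up to 2 Hz past its nominal
band (`carrier_pad_hz`), but never into another band's nominal range:
adjacent bands already supply effect-scaled content, and overlapping
carriers would add cross-term variance. With the default contiguous bands
the entire 2–32 Hz range is effect-scaled in motor channels, so the broad
Morlet kernels at band edges see fully scaled power and the recovered
contrast is not diluted. Residual negative bias of the recovered alpha
contrast (≈ 0.1–0.2 dB, from the un-scaled 1/f background under the
kernels and from ramp samples entering edge wavelets) is well inside the
±0.5 dB recovery tolerance the tests assert.

**Unrelated channels.** PO7/PO8 share one posterior rhythm generator per
band (amplitude 2× the motor base — posterior rhythms dominate scalp EEG)
projected with opposite signs, like the two poles of a dipolar field.
Their contribution to the montage average is therefore zero: the common
average reference neither injects posterior alpha into the motor channels
nor carries any of the motor-channel effect into the controls beyond the
unavoidable 1/8 montage-mean term. Unrelated carriers are deliberately
*not* segment-calibrated, so these channels keep natural trial-to-trial
spectral variability; the residual reference leakage (~0.1 dB) stays far
below their within-subject noise, which is what a valid negative control
requires. These are the two features a dense real montage provides
statistically and an 8-channel stand-in must provide by construction.

**What the generator does not emulate:** eye-blink/muscle artefacts
(rejection is exercised with injected square pulses in the tests),
volume-conducted correlation between motor channels, non-stationary
background drift, between-trial force variability, and EMG/force channels.
Passing tests therefore demonstrate correctness of the estimators and
inference under a calibrated, stationary-background model — not robustness
to every artefact class of real scalp EEG.

## Numerical choices

- dB comparisons in tests at 1e−6 absolute unless stated; gain-model
  invariance asserted at 1e−9 dB.
- Degenerate RM-ANOVA cells (all conditions identical) give F = 0, p = 1;
  the zero-variance test is relative to the data scale (1e−12·SS_total),
  not exact equality.
- Remainder trials of the 3-way split are dropped from the end (the
  latest trials).
- The 16-bit EDF writer scales to a symmetric physical range
  (±⌈max|x|⌉ µV), zero-pads the last 1 s record and stores the true
  sample count in the JSON events sidecar; reading goes through
  `mne.io.read_raw_edf`.
- Cohort seeding: subject j of a cohort with seed s uses RNG stream
  s + j; replicate r of a power study uses cohort seed s + 1000·r so no
  two replicates share a stream.

## Problem sizes

The test suite and the acceptance script run the replicate power studies
with the analysis restricted to C3 (plus the PO7 control) and the alpha
frequency grid — restriction to channels and frequencies changes none of
the per-replicate estimates, only the amount of untested computation. The
test suite uses 100 replicates for the type-I-error and power properties;
the acceptance script reports the same rates from 30 replicates (the
replicate count is recorded in its output as `n`).

## Known limitations

- Channel-level only: no source reconstruction, no IC clustering.
- The Morlet cycle scheme (3 cycles at 3 Hz, square-root expansion,
  50 ms step) is one reasonable member of the standard family; absolute
  ERSP values depend on it, although the gain model removes overall scale.
- The amplitude-threshold rejector is not calibrated against human
  artefact statistics.
- With only 8 montage channels the common average reference is a much
  poorer reference than with a dense net; the generator's dipole-paired
  unrelated rhythms compensate by construction (see above).
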