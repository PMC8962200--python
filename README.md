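# fatiguersp

Event-related spectral perturbation (ERSP) analysis of graded motor
fatigue in intermittent-contraction EEG.

## The problem

When a person repeats a submaximal contraction (say, 5 s elbow flexions at
40 % of maximal force, with 2 s rest) until exhaustion, fatigue builds
steadily over the session. The EEG band power over sensorimotor cortex is
expected to track that build-up. Because the fatigue level is not directly
observable trial by trial, the session's trials are split into
chronological thirds — minimum (MinFatg), moderate (ModFatg) and severe
(SevFatg) fatigue — and only the first, middle and last 10 % of trials of
the respective thirds are compared, so the groups are maximally separated
in time.

`fatiguersp` provides, for researchers working with task-marked scalp EEG:

- a **preprocessing chain** (zero-phase 1–100 Hz FIR band-pass, 60 Hz
  notches, common average reference, onset/offset epoching with pre-onset
  baseline substitution, amplitude-threshold epoch rejection,
  chronological condition assignment and 10 % trial selection);
- the **ERSP estimator family** under the gain model with a
  *cross-condition common baseline*,

  `ERSP(f,t) = 10·log10[ ERS(f,t) ⁄ B_AVG(f) ]`,

  where `ERS(f,t)` is the Morlet wavelet power averaged over a
  condition's M trials and `B_AVG(f)` pools the pre-contraction baseline
  power over the selected trials of **all three** conditions (p trials,
  q time points) — so fatigue-induced drift of the baseline itself cannot
  masquerade as a task effect — plus its time-averaged (`ERSP~`) and
  band-averaged (`ERSP≈`, `B≈`) summaries;
- **inference**: surrogate permutation tests (repeated-measures F
  statistic, condition labels permuted within subject, 2000 permutations)
  with Benjamini–Hochberg FDR masks, and one-way repeated-measures ANOVA
  with Bonferroni-corrected paired post-hoc comparisons;
- **classification**: 12-dimensional single-trial ERSP feature vectors
  (six motor channels × alpha/beta) fed to a linear SVM under stratified
  10-fold cross-validation;
- a **synthetic cohort generator** that emulates the task protocol
  (event-marked contractions, 1/f background, 60 Hz line, band-limited
  oscillations whose power steps up with the fatigue condition in motor
  channels only), so the whole pipeline is testable end to end without
  any data download.

Real recordings enter as EDF files with a JSON events sidecar
(`read_edf` / `FatigueSpectralModel.from_directory`); synthetic cohorts
are written to the same format.

## Worked example

```python
import numpy as np
from fatiguersp import SimConfig, simulate_cohort, FatigueSpectralModel

config = SimConfig(n_subjects=14, n_trials=60, seed=0)
recordings = simulate_cohort(config)

model = FatigueSpectralModel(
    recordings, window="steady", channels=["C3", "CP1", "PO7"],
    freqs=np.arange(4.0, 31.0),
)
results = model.fit()
print(results.summary())
print(f"Sev-Min alpha contrast at C3: "
      f"{results.contrast('C3', 'alpha'):+.2f} dB")
perm = results.permutation_spectrum("C3", n_perm=2000, seed=0)
print(f"FDR-significant frequencies at C3: "
      f"{model.freqs[perm.fdr_mask].astype(int).min()}-"
      f"{model.freqs[perm.fdr_mask].astype(int).max()} Hz "
      f"({int(perm.fdr_mask.sum())} of {len(model.freqs)} grid points)")
```

prints

```
Fatigue-graded ERSP analysis (steady window, 14 subjects)
========================================================================
channel  band          F          p   Min-Mod   Min-Sev   Mod-Sev
------------------------------------------------------------------------
C3       theta     40.52   1.02e-08  2.85e-03  3.91e-08  6.70e-03
C3       alpha     22.44   2.18e-06  5.52e-04  1.31e-05  1.16e-01
C3       beta      41.97   7.24e-09  2.78e-03  2.19e-08  4.87e-03
CP1      theta     46.63   2.51e-09  4.33e-04  2.34e-08  1.20e-02
CP1      alpha     23.90   1.29e-06  3.97e-04  6.42e-06  1.75e-01
CP1      beta      42.86   5.87e-09  2.62e-04  7.47e-08  1.84e-02
PO7      theta      1.06   3.61e-01        --        --        --
PO7      alpha      0.16   8.56e-01        --        --        --
PO7      beta       0.31   7.38e-01        --        --        --
------------------------------------------------------------------------
pairwise p-values are Bonferroni-adjusted; '--' marks channels/bands whose omnibus ANOVA p >= 0.05

Sev-Min alpha contrast at C3: +2.76 dB
FDR-significant frequencies at C3: 4-30 Hz (27 of 27 grid points)
```

Reading it: at the motor channels (C3, CP1) the band power rises
monotonically with the fatigue condition — the omnibus F is large, the
Min–Sev comparison is the strongest pairwise difference, and the recovered
Sev−Min alpha contrast (+2.76 dB) sits close to the +3 dB the generator
injected (the shortfall is the un-scaled 1/f background under the wavelet
kernels plus the 1 dB between-subject spread at this seed). The unrelated
posterior channel PO7 carries no effect, so its ANOVA is null and the
post-hoc columns are gated off (`--`) — the negative control for the
chronological design. The permutation/FDR mask flags the whole injected
4–30 Hz range.

The same analysis runs from a shell via the `fatiguersp` CLI
(`simulate`, `preprocess`, `ersp`, `stats`, `classify`, `run-all`,
`validate`), driven by one YAML config; `run-all` writes the ERSP table,
the ANOVA/post-hoc CSV, the permutation mask, the classification report
and a manifest with every seed and a config hash.

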