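"""Event-related spectral perturbation (ERSP) under the gain model.

Estimator family, per channel and fatigue condition:

* ``ERS(f, t)``   - mean Morlet wavelet power across a condition's M trials;
* ``B_AVG(f)``    - the *common* baseline: power pooled over the selected
  trials of all three fatigue conditions and the valid baseline time points
  (p trials, q(f) points), so fatigue-induced baseline drift does not
  distort condition contrasts;
* ``ERSP(f, t)``  = 10 log10(ERS(f, t) / B_AVG(f))  [dB, gain model];
* ``ERSP~(f)``    - ERSP averaged over the r task-window time points
  (steady contraction 1-3 s after onset, or post-contraction 0.25-1.25 s
  after offset);
* ``ERSP= / B=``  - ERSP~ / baseline dB further averaged over a frequency
  band, one scalar per condition.

The time-frequency estimator is a Morlet wavelet transform on a linear
3-90 Hz grid with cycles growing as ``n_cycles(f) = c0 * (f / f_min)^e``
(default c0=3, e=0.5) and a nominal 50 ms output step.  Grid points whose
wavelet support overruns the epoch edge are marked invalid and excluded
from every average, so the baseline point count q and task point count r
reflect only clean estimates.
"""

from __future__ import annotations

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .containers import (
    CONDITIONS,
    DEFAULT_BANDS,
    UNASSIGNED,
    ConfigurationError,
    BaselineSpectrum,
    EpochSet,
    ErspResult,
    StructureError,
    TFPower,
)

#: Task-window limits (s) per window kind, half-open.
TASK_WINDOWS = {"steady": (1.0, 3.0), "post": (0.25, 1.25)}
#: Baseline-window limits (s) per window kind, half-open.
BASELINE_WINDOWS = {"steady": (-1.5, -0.5), "post": (-4.0, -3.0)}

DEFAULT_FREQS = np.arange(3.0, 91.0)
DEFAULT_CYCLES = (3.0, 0.5)
DEFAULT_TIME_STEP = 0.05


#: Reference frequency anchoring the cycle-expansion scheme (Hz).
CYCLES_BASE_FREQ = 3.0


def morlet_cycles(freqs: np.ndarray, cycles_spec=DEFAULT_CYCLES) -> np.ndarray:
    """Cycles per frequency: ``c0 * (f / 3 Hz)^expansion``.

    Anchored at the canonical 3 Hz grid base (not the first grid point), so
    a restricted frequency grid uses the same wavelets as the full one.
    """
    c0, expansion = cycles_spec
    freqs = np.asarray(freqs, dtype=float)
    return c0 * (freqs / CYCLES_BASE_FREQ) ** expansion


def tf_decompose(epochs: EpochSet, channel: str,
                 freqs: np.ndarray | None = None,
                 cycles_spec: tuple[float, float] = DEFAULT_CYCLES,
                 time_step: float = DEFAULT_TIME_STEP,
                 retained_only: bool = True) -> TFPower:
    """Morlet wavelet power for one channel of an epoch set.

    Output times are the epoch samples nearest a nominal ``time_step`` grid.
    ``valid[i, j]`` is False where the wavelet at ``freqs[i]`` (support
    +-5 sigma_t, sigma_t = n_cycles / (2 pi f)) extends past the epoch.
    """
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    n_cycles = morlet_cycles(freqs, cycles_spec)
    fs = epochs.sampling_rate
    times = epochs.times

    half_support = 5.0 * n_cycles / (2.0 * np.pi * freqs)
    epoch_dur = epochs.n_samples / fs
    too_long = 2 * half_support >= epoch_dur
    if np.any(too_long):
        raise ConfigurationError(
            f"epoch too short for wavelet at {freqs[too_long][0]:g} Hz "
            f"(needs {2 * half_support[too_long][0]:.2f} s)"
        )

    sel = epochs.retained if retained_only else np.ones(epochs.n_trials, bool)
    data = epochs.data[sel, epochs.channel_index(channel), :][:, None, :]
    power = tfr_array_morlet(
        data, sfreq=fs, freqs=freqs, n_cycles=n_cycles,
        output="power", zero_mean=True, verbose="error",
    )[:, 0]  # trials x freqs x samples

    # snap a nominal time_step grid onto the sample grid
    nominal = np.arange(times[0], times[-1] + 1e-9, time_step)
    idx = np.unique(np.round((nominal - times[0]) * fs).astype(int))
    idx = idx[idx < epochs.n_samples]
    out_times = times[idx]

    valid = (out_times[None, :] >= times[0] + half_support[:, None]) & \
            (out_times[None, :] <= times[-1] - half_support[:, None])

    return TFPower(
        power=power[:, :, idx], freqs=freqs, times=out_times,
        condition=epochs.condition[sel].copy(), channel=channel,
        anchor=epochs.anchor, valid=valid, subject_id=epochs.subject_id,
    )


def compute_ers(tf: TFPower, condition: str) -> np.ndarray:
    """Mean power across the condition's M trials at each (f, t) point."""
    members = tf.trials_in(condition)
    if len(members) == 0:
        raise StructureError(f"no trials in condition {condition!r}")
    return tf.power[members].mean(axis=0)


def _window_mask(tf: TFPower, window: tuple[float, float]) -> np.ndarray:
    """Per-(f, t) mask of valid points inside the half-open window."""
    in_win = (tf.times >= window[0] - 1e-9) & (tf.times < window[1] - 1e-9)
    return tf.valid & in_win[None, :]


def compute_common_baseline(tf: TFPower,
                            baseline_window: tuple[float, float],
                            conditions=None) -> BaselineSpectrum:
    """Pool baseline power over the selected trials of the conditions.

    ``b_avg(f)`` averages the power of the p condition-labelled trials over
    the q(f) valid baseline time points at each frequency.  By default all
    three fatigue conditions are pooled (the common baseline that keeps
    fatigue-induced baseline drift out of condition contrasts); pass e.g.
    ``conditions=("MinFatg",)`` for a minimum-fatigue-only baseline.
    """
    if conditions is None:
        selected = np.flatnonzero(tf.condition != UNASSIGNED)
    else:
        selected = np.flatnonzero(np.isin(tf.condition, list(conditions)))
    if len(selected) == 0:
        raise StructureError("no condition-labelled trials to pool")
    mask = _window_mask(tf, baseline_window)
    q = mask.sum(axis=1)
    if np.any(q == 0):
        raise StructureError(
            "baseline window contains no valid time points at some frequency"
        )
    pw = tf.power[selected]  # p x f x t
    b_avg = np.array([
        pw[:, i, mask[i]].mean() for i in range(len(tf.freqs))
    ])
    if np.any(b_avg <= 0):
        raise StructureError("degenerate (zero) baseline power")
    return BaselineSpectrum(
        b_avg=b_avg, freqs=tf.freqs, p=len(selected), q=q,
        window=tuple(baseline_window),
    )


def compute_ersp(ers: np.ndarray, baseline: BaselineSpectrum) -> np.ndarray:
    """Gain-model ERSP in dB: 10 log10(ERS(f, t) / B_AVG(f))."""
    ers = np.asarray(ers, dtype=float)
    if np.any(ers <= 0):
        raise StructureError("non-positive ERS power; log-ratio undefined")
    return 10.0 * np.log10(ers / baseline.b_avg[:, None])


def time_average_ersp(ersp_tf: np.ndarray, tf: TFPower,
                      window: tuple[float, float]) -> np.ndarray:
    """Mean dB over the r valid task-window time points, per frequency."""
    mask = _window_mask(tf, window)
    if not mask.any(axis=1).all():
        raise StructureError(
            "task window contains no valid time points at some frequency"
        )
    return np.array([
        ersp_tf[i, mask[i]].mean() for i in range(len(tf.freqs))
    ])


def band_average(values: np.ndarray, freqs: np.ndarray,
                 band: tuple[float, float]) -> np.ndarray | float:
    """Mean over grid frequencies with band_low <= f < band_high.

    Accepts a per-frequency vector (returns a scalar) or a stacked
    subjects x frequencies matrix (returns one scalar per row).
    """
    values = np.asarray(values, dtype=float)
    sel = (freqs >= band[0]) & (freqs < band[1])
    if not sel.any():
        raise ConfigurationError(
            f"band {band} does not overlap the frequency grid"
        )
    if values.ndim == 1:
        return float(values[sel].mean())
    return values[..., sel].mean(axis=-1)


def baseline_condition_summary(tf: TFPower, baseline: BaselineSpectrum,
                               band: tuple[float, float],
                               condition: str) -> float:
    """Band-averaged condition baseline in dB relative to the common baseline.

    The condition's baseline spectrum B_c(f) (mean power over its trials
    and the valid baseline time points) is expressed as the gain-model
    ratio 10 log10(B_c(f) / B_AVG(f)) and band-averaged.
    """
    members = tf.trials_in(condition)
    if len(members) == 0:
        raise StructureError(f"no trials in condition {condition!r}")
    mask = _window_mask(tf, baseline.window)
    pw = tf.power[members]
    b_cond = np.array([
        pw[:, i, mask[i]].mean() for i in range(len(tf.freqs))
    ])
    if np.any(b_cond <= 0):
        raise StructureError("degenerate condition baseline power")
    db = 10.0 * np.log10(b_cond / baseline.b_avg)
    return band_average(db, tf.freqs, band)


def ersp_analysis(tf: TFPower, window_kind: str = "steady",
                  bands: dict[str, tuple[float, float]] | None = None,
                  baseline: BaselineSpectrum | None = None,
                  baseline_conditions=None) -> ErspResult:
    """Full per-channel ERSP summary for one subject.

    Computes the common baseline (unless one is supplied), per-condition
    ERSP maps, time-averaged spectra over the task window, and band-averaged
    task/baseline scalars for every (condition, band).
    ``baseline_conditions`` restricts the baseline pool (for instance to
    MinFatg only); the default pools all three conditions.
    """
    if window_kind not in TASK_WINDOWS:
        raise ConfigurationError("window_kind must be 'steady' or 'post'")
    expected_anchor = "onset" if window_kind == "steady" else "offset"
    if tf.anchor != expected_anchor:
        raise ConfigurationError(
            f"{window_kind!r} analysis needs {expected_anchor}-anchored epochs"
        )
    if bands is None:
        bands = {k: v for k, v in DEFAULT_BANDS.items() if k != "gamma"}
    bands = {
        name: edges for name, edges in bands.items()
        if np.any((tf.freqs >= edges[0]) & (tf.freqs < edges[1]))
    }
    if not bands:
        raise ConfigurationError("no band overlaps the frequency grid")
    task_window = TASK_WINDOWS[window_kind]
    if baseline is None:
        baseline = compute_common_baseline(
            tf, BASELINE_WINDOWS[window_kind], conditions=baseline_conditions
        )

    ersp_tf, ersp_vec = {}, {}
    band_scalar, baseline_scalar = {}, {}
    for cond in CONDITIONS:
        ers = compute_ers(tf, cond)
        ersp_tf[cond] = compute_ersp(ers, baseline)
        ersp_vec[cond] = time_average_ersp(ersp_tf[cond], tf, task_window)
        for bname, bedges in bands.items():
            band_scalar[(cond, bname)] = band_average(
                ersp_vec[cond], tf.freqs, bedges
            )
            baseline_scalar[(cond, bname)] = baseline_condition_summary(
                tf, baseline, bedges, cond
            )
    return ErspResult(
        channel=tf.channel, window_kind=window_kind, window=task_window,
        freqs=tf.freqs, times=tf.times, ersp_tf=ersp_tf,
        ersp_time_avg=ersp_vec, band_scalar=band_scalar,
        baseline_scalar=baseline_scalar, baseline=baseline,
        subject_id=tf.subject_id,
    )
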