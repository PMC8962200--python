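"""Channel-level preprocessing: filtering, re-referencing, epoching,
rejection, and chronological fatigue-condition assignment.

The stages mirror a standard scalp-EEG cleaning chain for an intermittent
motor task: zero-phase Hamming-windowed sinc FIR band-pass (1-100 Hz) with
FIR notches at the 60 Hz line frequency and its harmonics, common average
reference, onset epochs spanning [-1.5, 5.0) s and offset epochs spanning
[-4.0, 2.0) s (with the pre-onset baseline swapped into the [-4.0, -2.5) s
span of each offset epoch), an amplitude-threshold epoch rejector, and the
partition of retained trials into chronological thirds labelled MinFatg /
ModFatg / SevFatg with first / middle / last 10 % trial selection.

Sample-index convention: 0-based, half-open windows [t_start, t_end);
epoch sample counts are round(duration x rate).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from mne.filter import filter_data, notch_filter

from .containers import (
    CONDITIONS,
    UNASSIGNED,
    ConfigurationError,
    EpochSet,
    Recording,
    StructureError,
)

logger = logging.getLogger(__name__)

#: Onset epoch limits (s relative to "Start"), half-open.
ONSET_WINDOW = (-1.5, 5.0)
#: Offset epoch limits (s relative to "End"), half-open.
OFFSET_WINDOW = (-4.0, 2.0)
#: Span of each offset epoch replaced by the trial's pre-onset baseline.
SWAP_WINDOW = (-4.0, -2.5)
#: Pre-onset span supplying the swapped baseline (s relative to "Start").
PRE_ONSET_BASELINE = (-1.5, 0.0)


def filter_recording(rec: Recording, low: float = 1.0, high: float = 100.0,
                     notch_base: float = 60.0) -> Recording:
    """Zero-phase FIR band-pass then notch at the line frequency harmonics.

    The band-pass is a Hamming-windowed sinc FIR applied forward-backward
    (zero phase); notches are narrow FIR band-stops (+-1 Hz) at
    ``notch_base`` and every harmonic strictly below ``high``.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < low < high:
        raise ConfigurationError("need 0 < low < high")
    if high >= nyq:
        raise ConfigurationError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    # 0.6 Hz low transition band: sub-Hz drift must sit in the stop band,
    # not halfway down the default (1 Hz wide) transition slope
    data = filter_data(
        rec.data, rec.sampling_rate, l_freq=low, h_freq=high,
        l_trans_bandwidth=min(0.6, low * 0.6),
        fir_window="hamming", fir_design="firwin", phase="zero",
        verbose="error",
    )
    harmonics = np.arange(notch_base, high, notch_base)
    if len(harmonics):
        data = notch_filter(
            data, rec.sampling_rate, freqs=harmonics, method="fir",
            notch_widths=2.0, fir_window="hamming", fir_design="firwin",
            phase="zero", verbose="error",
        )
    return replace(rec, data=data)


def rereference_car(rec: Recording) -> Recording:
    """Common average reference: subtract the instantaneous channel mean."""
    if rec.n_channels < 2:
        raise ConfigurationError("common average reference needs >= 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def _epoch(rec: Recording, anchors: np.ndarray, window: tuple[float, float],
           anchor_name: str) -> tuple[np.ndarray, list[int]]:
    fs = rec.sampling_rate
    n_pre = round(-window[0] * fs)
    n_post = round(window[1] * fs)
    epochs, kept = [], []
    for i, a in enumerate(anchors):
        lo, hi = a - n_pre, a + n_post
        if lo < 0 or hi > rec.n_samples:
            logger.warning(
                "dropping trial %d: %s at sample %d lacks %g s context",
                i, anchor_name, a, -window[0] if lo < 0 else window[1],
            )
            continue
        epochs.append(rec.data[:, lo:hi])
        kept.append(i)
    if not epochs:
        raise StructureError("no trials with sufficient context to epoch")
    return np.stack(epochs), kept


def epoch_onset(rec: Recording) -> EpochSet:
    """One epoch per "Start" event spanning [-1.5, 5.0) s around it.

    Trials whose epoch would overrun the recording are dropped with a
    logged warning.  At 250 Hz each epoch holds 1625 samples.
    """
    starts = rec.event_samples("Start")
    if len(starts) == 0:
        raise StructureError("recording has no Start events")
    data, kept = _epoch(rec, starts, ONSET_WINDOW, "Start")
    return EpochSet(
        data=data, anchor="onset", t0_offset_s=ONSET_WINDOW[0],
        sampling_rate=rec.sampling_rate, channel_labels=list(rec.channel_labels),
        trial_order=np.array(kept), subject_id=rec.subject_id,
    )


def epoch_offset_with_baseline_swap(rec: Recording) -> EpochSet:
    """Offset epochs spanning [-4, 2) s around "End", with baseline swap.

    Within each epoch the samples in [-4.0, -2.5) s are replaced by the
    same trial's pre-onset samples [-1.5, 0.0) s relative to its "Start",
    so the baseline read from offset epochs is genuine resting data rather
    than mid-contraction signal.
    """
    pairs = rec.trial_pairs()
    fs = rec.sampling_rate
    n_pre = round(-OFFSET_WINDOW[0] * fs)
    n_post = round(OFFSET_WINDOW[1] * fs)
    n_swap = round((SWAP_WINDOW[1] - SWAP_WINDOW[0]) * fs)
    n_base = round(-PRE_ONSET_BASELINE[0] * fs)
    epochs, kept = [], []
    for i, (start, end) in enumerate(pairs):
        lo, hi = end - n_pre, end + n_post
        if lo < 0 or hi > rec.n_samples or start - n_base < 0:
            logger.warning(
                "dropping trial %d: offset epoch at sample %d overruns recording",
                i, end,
            )
            continue
        ep = rec.data[:, lo:hi].copy()
        ep[:, :n_swap] = rec.data[:, start - n_base:start]
        epochs.append(ep)
        kept.append(i)
    if not epochs:
        raise StructureError("no trials with sufficient context to epoch")
    return EpochSet(
        data=np.stack(epochs), anchor="offset", t0_offset_s=OFFSET_WINDOW[0],
        sampling_rate=rec.sampling_rate, channel_labels=list(rec.channel_labels),
        trial_order=np.array(kept), subject_id=rec.subject_id,
    )


def reject_noisy_epochs(epochs: EpochSet,
                        peak_to_peak_limit: float = 200.0) -> EpochSet:
    """Flag trials whose peak-to-peak amplitude exceeds the limit anywhere.

    An automated stand-in for visual inspection: a trial is rejected when
    any channel's within-epoch peak-to-peak amplitude exceeds
    ``peak_to_peak_limit`` (microvolts).  Chronological order is preserved;
    raises if every trial would be rejected.
    """
    if peak_to_peak_limit <= 0:
        raise ConfigurationError("peak_to_peak_limit must be positive")
    out = epochs.copy()
    ptp = out.data.max(axis=2) - out.data.min(axis=2)  # trials x channels
    bad = (ptp > peak_to_peak_limit).any(axis=1)
    out.rejected = out.rejected | bad
    out.condition[out.rejected] = UNASSIGNED
    if out.rejected.all():
        raise StructureError("all trials rejected at this amplitude limit")
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("rejected %d/%d trials above %g uV peak-to-peak",
                    n_bad, out.n_trials, peak_to_peak_limit)
    return out


def assign_fatigue_conditions(epochs: EpochSet) -> EpochSet:
    """Partition retained trials into chronological thirds.

    The first floor(T/3) retained trials become MinFatg, the next third
    ModFatg, the next SevFatg; the trailing T mod 3 trials stay unassigned.
    """
    out = epochs.copy()
    retained = np.flatnonzero(out.retained)
    T = len(retained)
    if T < 3:
        raise StructureError(f"need >= 3 retained trials, have {T}")
    size = T // 3
    out.condition[:] = UNASSIGNED
    for c, cond in enumerate(CONDITIONS):
        out.condition[retained[c * size:(c + 1) * size]] = cond
    return out


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def select_condition_trials(epochs: EpochSet, fraction: float = 0.10) -> EpochSet:
    """Keep the first/middle/last ``fraction`` of each condition's trials.

    ``n_sel = max(1, round(fraction * T_retained))`` trials are kept per
    condition: the first n_sel of MinFatg, the centred n_sel of ModFatg
    (start offset floor((set_size - n_sel)/2) within the set), and the last
    n_sel of SevFatg.  Every other trial is set to unassigned, so the three
    selected groups are maximally separated in session time.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    out = epochs.copy()
    if fraction == 1:  # keep every assigned trial
        return out
    T = out.n_retained
    n_sel = max(1, _round_half_away(fraction * T))
    keep = np.zeros(out.n_trials, dtype=bool)
    for cond in CONDITIONS:
        members = np.flatnonzero(out.condition == cond)
        size = len(members)
        if n_sel > size:
            raise ConfigurationError(
                f"n_sel={n_sel} exceeds {cond} set size {size}"
            )
        if cond == "MinFatg":
            sel = members[:n_sel]
        elif cond == "ModFatg":
            start = (size - n_sel) // 2
            sel = members[start:start + n_sel]
        else:
            sel = members[size - n_sel:]
        keep[sel] = True
    out.condition[~keep] = UNASSIGNED
    return out


def preprocess_recording(rec: Recording, anchor: str = "onset",
                         low: float = 1.0, high: float = 100.0,
                         notch_base: float = 60.0,
                         peak_to_peak_limit: float = 200.0,
                         fraction: float = 0.10,
                         channels=None) -> EpochSet:
    """Full chain: CAR -> (pick) -> filter -> epoch -> reject -> assign -> select.

    The common average reference always uses the full montage; because CAR
    and the FIR filters are linear and commute, re-referencing before
    optionally restricting to ``channels`` gives the same result as
    filtering everything first, at a fraction of the cost.
    """
    rec = rereference_car(rec)
    if channels is not None:
        rec = rec.pick(channels)
    rec = filter_recording(rec, low, high, notch_base)
    if anchor == "onset":
        epochs = epoch_onset(rec)
    elif anchor == "offset":
        epochs = epoch_offset_with_baseline_swap(rec)
    else:
        raise ConfigurationError("anchor must be 'onset' or 'offset'")
    epochs = reject_noisy_epochs(epochs, peak_to_peak_limit)
    epochs = assign_fatigue_conditions(epochs)
    return select_condition_trials(epochs, fraction)
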