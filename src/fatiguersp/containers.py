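"""Core data containers shared across the analysis stages.

The pipeline moves data through four representations: a continuous
:class:`Recording` (channels x samples, microvolts) with task event markers,
an :class:`EpochSet` (trials x channels x samples anchored to task onset or
offset), per-channel time-frequency power (:class:`TFPower`), and the
baseline spectrum (:class:`BaselineSpectrum`) pooled across fatigue
conditions that normalises event-related spectral perturbation (ERSP)
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: The three graded fatigue conditions, in chronological order.
CONDITIONS = ("MinFatg", "ModFatg", "SevFatg")

#: Label for trials not assigned to any fatigue condition.
UNASSIGNED = "unassigned"

#: Default EEG frequency bands (Hz, half-open intervals [low, high)).
DEFAULT_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 90.0),
}

#: Scalp channels over the contralateral sensorimotor cortex used for the
#: channel-level analysis.
MOTOR_CHANNELS = ("FC3", "C1", "C3", "C5", "CP1", "CP3")


class ConfigurationError(ValueError):
    """Invalid parameter or configuration value."""


class StructureError(ValueError):
    """Malformed event structure or inconsistent container shapes."""


@dataclass
class Recording:
    """Continuous multichannel EEG with task onset/offset event markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_labels : sequence of str
    events : list of (str, int)
        ``("Start", sample)`` / ``("End", sample)`` markers, strictly
        alternating beginning with ``"Start"``.
    subject_id : str
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: Sequence[str]
    events: list[tuple[str, int]]
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise StructureError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise StructureError("channel_labels length must match data rows")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        self._validate_events()

    def _validate_events(self) -> None:
        samples = [s for _, s in self.events]
        if any(s2 <= s1 for s1, s2 in zip(samples, samples[1:])):
            raise StructureError("event samples must be strictly increasing")
        for i, (label, s) in enumerate(self.events):
            expected = "Start" if i % 2 == 0 else "End"
            if label != expected:
                raise StructureError(
                    f"event {i} is {label!r}, expected {expected!r} "
                    "(Start/End must alternate starting with Start)"
                )
            if not 0 <= s < self.n_samples:
                raise StructureError(f"event sample {s} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def event_samples(self, label: str) -> np.ndarray:
        return np.array([s for lab, s in self.events if lab == label], dtype=int)

    def trial_pairs(self) -> list[tuple[int, int]]:
        """Paired (start, end) samples, one per trial."""
        starts = self.event_samples("Start")
        ends = self.event_samples("End")
        if len(starts) != len(ends):
            raise StructureError("unpaired Start/End events")
        return list(zip(starts.tolist(), ends.tolist()))

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Return a copy restricted to the given channel labels."""
        idx = [list(self.channel_labels).index(lab) for lab in labels]
        return replace(
            self, data=self.data[idx].copy(), channel_labels=list(labels)
        )

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            events=list(self.events),
        )


@dataclass
class EpochSet:
    """Trials x channels x samples anchored to task onset or offset.

    ``t0_offset_s`` is the epoch start relative to the anchor event
    (-1.5 s for onset epochs, -4.0 s for offset epochs).  Sample windows are
    half-open: epoch sample ``i`` holds continuous sample
    ``anchor + round(t0_offset_s * rate) + i``.
    """

    data: np.ndarray
    anchor: str
    t0_offset_s: float
    sampling_rate: float
    channel_labels: Sequence[str]
    trial_order: np.ndarray
    condition: np.ndarray = field(default=None)
    rejected: np.ndarray = field(default=None)
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise StructureError("data must be 3-D (trials x channels x samples)")
        if self.anchor not in ("onset", "offset"):
            raise ConfigurationError("anchor must be 'onset' or 'offset'")
        n = self.data.shape[0]
        self.trial_order = np.asarray(self.trial_order, dtype=int)
        if np.any(np.diff(self.trial_order) <= 0):
            raise StructureError("trial_order must be strictly increasing")
        if self.condition is None:
            self.condition = np.full(n, UNASSIGNED, dtype=object)
        else:
            self.condition = np.asarray(self.condition, dtype=object)
        if self.rejected is None:
            self.rejected = np.zeros(n, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
        if not (len(self.trial_order) == len(self.condition)
                == len(self.rejected) == n):
            raise StructureError("per-trial metadata length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Epoch sample times in seconds relative to the anchor."""
        return self.t0_offset_s + np.arange(self.n_samples) / self.sampling_rate

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of trials that survived epoch rejection."""
        return ~self.rejected

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def channel_index(self, label: str) -> int:
        try:
            return list(self.channel_labels).index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            trial_order=self.trial_order.copy(),
            condition=self.condition.copy(),
            rejected=self.rejected.copy(),
        )


@dataclass
class TFPower:
    """Single-channel Morlet wavelet power, per trial.

    ``power[k, i, j]`` is the wavelet power of trial ``k`` at frequency
    ``freqs[i]`` and time ``times[j]`` (seconds relative to the epoch
    anchor).  ``valid[i, j]`` is False where the wavelet support at that
    frequency overruns the epoch edge; such points are excluded from every
    average downstream.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    condition: np.ndarray
    channel: str
    anchor: str
    valid: np.ndarray = field(default=None)
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.power.ndim != 3:
            raise StructureError("power must be trials x freqs x times")
        if np.any(self.power < 0):
            raise StructureError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise StructureError("freqs and times must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.power.shape[1:], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.power.shape[1:]:
            raise StructureError("valid mask shape mismatch")

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def trials_in(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.condition == condition)

    def trial_counts(self) -> dict[str, int]:
        """Trial count M per fatigue condition."""
        return {c: int(np.sum(self.condition == c)) for c in CONDITIONS}


@dataclass
class BaselineSpectrum:
    """Common pre-contraction baseline spectrum pooled across conditions.

    ``b_avg[i]`` is the mean baseline power at ``freqs[i]`` over all ``p``
    selected trials (all three fatigue conditions) and the ``q[i]`` valid
    baseline time points at that frequency.
    """

    b_avg: np.ndarray
    freqs: np.ndarray
    p: int
    q: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.b_avg = np.asarray(self.b_avg, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.q = np.asarray(self.q, dtype=int)
        if np.any(self.b_avg <= 0):
            raise StructureError(
                "baseline power must be strictly positive at every frequency"
            )
        if np.any(self.q <= 0):
            raise StructureError("every frequency needs >= 1 valid baseline point")


@dataclass
class ErspResult:
    """ERSP estimates for one channel at every aggregation level.

    ``ersp_tf`` maps condition -> ERSP(f, t) in dB (gain model against the
    common baseline); ``ersp_time_avg`` maps condition -> the time-averaged
    dB spectrum over the task window; ``band_scalar`` and ``baseline_scalar``
    map (condition, band) -> the band-averaged task (ERSP) and baseline (B)
    summaries in dB.
    """

    channel: str
    window_kind: str
    window: tuple[float, float]
    freqs: np.ndarray
    times: np.ndarray
    ersp_tf: dict[str, np.ndarray]
    ersp_time_avg: dict[str, np.ndarray]
    band_scalar: dict[tuple[str, str], float]
    baseline_scalar: dict[tuple[str, str], float]
    baseline: BaselineSpectrum = None
    subject_id: str = "S00"
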