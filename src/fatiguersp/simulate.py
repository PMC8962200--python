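"""Synthetic intermittent-contraction EEG with graded fatigue effects.

The generator emulates a prolonged intermittent motor task: repeated ~5 s
submaximal contractions separated by 2 s rest, cued by "Start"/"End" event
markers, recorded at 250 Hz from a handful of scalp channels.  Each channel
carries 1/f background noise, 60 Hz line contamination, and band-limited
oscillatory activity (theta/alpha/beta by default).  In motor channels the
band power is stepped up across the session's chronological thirds to mimic
the monotone power-fatigue relation the analysis is designed to detect;
"unrelated" channels carry no condition effect and serve as negative
controls.

Oscillations are amplitude-modulated narrowband Gaussian noise, not pure
tones, so time-frequency estimates have realistic variance.  The carrier is
RMS-normalised per task segment before the condition amplitude is applied,
which makes the injected band-power increments exact by construction (see
docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sfft
from scipy import signal

from .containers import (
    CONDITIONS,
    MOTOR_CHANNELS,
    ConfigurationError,
    Recording,
)

logger = logging.getLogger(__name__)

#: Default per-band oscillation settings: (band edges Hz, base RMS uV,
#: per-condition increments dB in motor channels).  All three bands share
#: the same monotone increment profile, emulating the finding that theta,
#: alpha and beta power all scale with the fatigue level.
DEFAULT_BAND_EFFECTS = {
    "theta": ((4.0, 8.0), 3.5, (0.0, 1.5, 3.0)),
    "alpha": ((8.0, 13.0), 9.0, (0.0, 1.5, 3.0)),
    "beta": ((13.0, 30.0), 3.5, (0.0, 1.5, 3.0)),
}


@dataclass
class BandEffect:
    """One oscillatory band: edges, base amplitude, fatigue increments.

    ``increments_db`` are the per-condition power increments (MinFatg,
    ModFatg, SevFatg) applied in motor channels during contractions; at
    ``rest_fraction`` of their dB value during rest.
    """

    low: float
    high: float
    base_rms: float
    increments_db: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ConfigurationError("band edges must satisfy 0 < low < high")
        if self.base_rms < 0:
            raise ConfigurationError("base_rms must be non-negative")
        if len(self.increments_db) != 3:
            raise ConfigurationError("need one increment per fatigue condition")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults follow the task protocol the analysis targets: 14 subjects,
    60 trials of 5 s contraction + 2 s rest at 250 Hz, six motor channels
    (FC3, C1, C3, C5, CP1, CP3) plus two unrelated channels, pink (1/f)
    background noise, 60 Hz line contamination, and monotone band-power
    increments across the session's chronological thirds with 1 dB
    between-subject spread.
    """

    n_subjects: int = 14
    channel_labels: tuple[str, ...] = MOTOR_CHANNELS + ("PO7", "PO8")
    motor_channels: tuple[str, ...] = MOTOR_CHANNELS
    sampling_rate: float = 250.0
    n_trials: int = 60
    contraction_s: float = 5.0
    rest_s: float = 2.0
    ramp_s: float = 1.0
    ramp_down_s: float = 0.25
    lead_in_s: float = 5.0
    lead_out_s: float = 5.0
    noise_exponent: float = 1.0
    noise_rms: float = 5.0
    line_freq: float = 60.0
    line_amp: float = 2.0
    band_effects: dict[str, BandEffect] = field(default_factory=lambda: {
        name: BandEffect(lo_hi[0], lo_hi[1], rms, inc)
        for name, (lo_hi, rms, inc) in DEFAULT_BAND_EFFECTS.items()
    })
    rest_fraction: float = 0.5
    between_subject_sd: float = 1.0
    effect_profile: str = "step"
    carrier_pad_hz: float = 2.0
    unrelated_amp_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        for name in ("sampling_rate", "contraction_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.effect_profile not in ("step", "linear"):
            raise ConfigurationError("effect_profile must be 'step' or 'linear'")
        if not 0 <= self.rest_fraction <= 1:
            raise ConfigurationError("rest_fraction must be in [0, 1]")
        missing = set(self.motor_channels) - set(self.channel_labels)
        if missing:
            raise ConfigurationError(f"motor channels absent from labels: {missing}")

    # -- derived sample geometry ------------------------------------------
    @property
    def samples_per_trial(self) -> int:
        return round((self.contraction_s + self.rest_s) * self.sampling_rate)

    @property
    def contraction_samples(self) -> int:
        return round(self.contraction_s * self.sampling_rate)

    @property
    def n_samples(self) -> int:
        return (round(self.lead_in_s * self.sampling_rate)
                + self.n_trials * self.samples_per_trial
                + round(self.lead_out_s * self.sampling_rate))

    def null(self) -> "SimConfig":
        """Copy of this config with every fatigue increment set to zero."""
        bands = {
            name: replace(b, increments_db=(0.0, 0.0, 0.0))
            for name, b in self.band_effects.items()
        }
        return replace(self, band_effects=bands, between_subject_sd=0.0)

    def trial_events(self) -> list[tuple[str, int]]:
        """Start/End markers shared by every subject (exact sample grid)."""
        n_lead = round(self.lead_in_s * self.sampling_rate)
        events = []
        for k in range(self.n_trials):
            start = n_lead + k * self.samples_per_trial
            events.append(("Start", start))
            events.append(("End", start + self.contraction_samples))
        return events

    def trial_condition_index(self, trial: int) -> int:
        """Chronological-third condition index (0=Min, 1=Mod, 2=Sev)."""
        return min(2, (3 * trial) // self.n_trials)

    def carrier_pads(self, name: str) -> tuple[float, float]:
        """Effective (lower, upper) pad for a band's carrier.

        Pads are clipped so no carrier overlaps another band's nominal
        range: adjacent bands supply their own effect-scaled content, and
        overlapping carriers would add avoidable cross-term variance.
        """
        band = self.band_effects[name]
        lo_limit = max(
            (b.high for b in self.band_effects.values() if b.high <= band.low),
            default=0.0,
        )
        hi_limit = min(
            (b.low for b in self.band_effects.values() if b.low >= band.high),
            default=self.sampling_rate / 2.0,
        )
        pad_lo = min(self.carrier_pad_hz, band.low - lo_limit)
        pad_hi = min(self.carrier_pad_hz, hi_limit - band.high)
        return max(pad_lo, 0.0), max(pad_hi, 0.0)


def injected_increments_db(config: SimConfig, subject_index: int) -> dict:
    """The per-band, per-condition dB increments a subject actually receives.

    Band increments are jittered per subject by ``between_subject_sd`` (dB)
    for the ModFatg and SevFatg conditions; MinFatg is the reference and is
    left at its configured value.  Deterministic given (seed, subject_index).
    """
    rng = np.random.default_rng(config.seed + subject_index)
    out = {}
    for name in sorted(config.band_effects):
        band = config.band_effects[name]
        inc = np.array(band.increments_db, dtype=float)
        jitter = rng.normal(0.0, config.between_subject_sd, size=2)
        inc[1:] = inc[1:] + jitter
        out[name] = {c: float(v) for c, v in zip(CONDITIONS, inc)}
    return out


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    Synthesised directly in the frequency domain (iid complex-Gaussian
    spectrum shaped by f^(-exponent/2)) on a fast FFT length, then
    truncated to n samples.
    """
    nfast = sfft.next_fast_len(n, real=True)
    freqs = sfft.rfftfreq(nfast, d=1.0 / fs)
    spec = np.zeros(len(freqs), dtype=complex)
    nonzero = freqs > 0
    m = int(nonzero.sum())
    draws = rng.standard_normal((m, 2))
    spec[nonzero] = (draws[:, 0] + 1j * draws[:, 1]) * (
        freqs[nonzero] ** (-exponent / 2.0)
    )
    x = sfft.irfft(spec, nfast)[:n]
    return x * (rms / np.std(x))


def _band_carrier(rng: np.random.Generator, n: int, fs: float,
                  low: float, high: float,
                  pad_lo: float = 0.0,
                  pad_hi: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited Gaussian noise plus its nominal-band component.

    The carrier occupies [low - pad_lo, high + pad_hi) so that spectral
    estimators whose kernels straddle the nominal band edges still see
    fully scaled power; the returned ``nominal`` component (restricted to
    [low, high)) is what segment calibration normalises against.  Both are
    synthesised from one iid complex-Gaussian spectrum.
    """
    nfast = sfft.next_fast_len(n, real=True)
    freqs = sfft.rfftfreq(nfast, d=1.0 / fs)
    lo = max(low - pad_lo, 0.5)
    hi = min(high + pad_hi, fs / 2.0)
    in_pad = (freqs >= lo) & (freqs < hi)
    m = int(in_pad.sum())
    draws = rng.standard_normal((m, 2))
    spec = np.zeros(len(freqs), dtype=complex)
    spec[in_pad] = draws[:, 0] + 1j * draws[:, 1]
    carrier = sfft.irfft(spec, nfast)[:n]
    if pad_lo == 0.0 and pad_hi == 0.0:
        nominal = carrier
    else:
        spec[(freqs < low) | (freqs >= high)] = 0.0
        nominal = sfft.irfft(spec, nfast)[:n]
    scale = np.std(nominal)
    return carrier / scale, nominal / scale


def _segment_bounds(config: SimConfig) -> list[tuple[int, int, bool]]:
    """(start, stop, is_contraction) sample segments tiling the recording."""
    fs = config.sampling_rate
    n_lead = round(config.lead_in_s * fs)
    segs = [(0, n_lead, False)]
    for k in range(config.n_trials):
        s0 = n_lead + k * config.samples_per_trial
        s1 = s0 + config.contraction_samples
        s2 = n_lead + (k + 1) * config.samples_per_trial
        segs.append((s0, s1, True))
        segs.append((s1, s2, False))
    segs.append((segs[-1][1], config.n_samples, False))
    return segs


def _normalise_carrier(carrier: np.ndarray, nominal: np.ndarray,
                       config: SimConfig) -> np.ndarray:
    """Scale the carrier to unit nominal-band RMS per task segment.

    Each segment's scale is set so the carrier's nominal-band component
    has unit RMS over that segment's *calibration window*: for
    contractions the steady interval
    (``ramp_s`` to ``ramp_s + 2 s`` after onset, the protocol's force
    plateau); for rest segments the pre-onset baseline interval (1.5 to
    0.5 s before the segment end, i.e. before the next contraction).  The
    injected band power is therefore exact in the windows the analysis
    reads.  The piecewise scale profile is smoothed with a short (0.1 s)
    Hann kernel so segment boundaries carry no broadband discontinuity.
    """
    fs = config.sampling_rate
    n_ramp = round(config.ramp_s * fs)
    n_steady = round(2.0 * fs)
    n_pre = round(1.5 * fs)
    n_gap = round(0.5 * fs)
    csum = np.concatenate(([0.0], np.cumsum(nominal ** 2)))

    bounds = _segment_bounds(config)
    seg_scale = np.ones(len(bounds))
    lengths = np.zeros(len(bounds), dtype=int)
    for i, (s0, s1, is_contraction) in enumerate(bounds):
        lengths[i] = max(s1 - s0, 0)
        if s1 <= s0:
            continue
        if is_contraction:
            ref0 = min(s0 + n_ramp, s1 - 1)
            ref1 = min(ref0 + n_steady, s1)
        else:
            ref0, ref1 = max(s0, s1 - n_pre), max(s0 + 1, s1 - n_gap)
        ms = (csum[ref1] - csum[ref0]) / (ref1 - ref0)
        if ms > 0:
            seg_scale[i] = 1.0 / np.sqrt(ms)
    scale = np.repeat(seg_scale, lengths)

    n_kern = 2 * round(0.05 * fs) + 1
    if n_kern >= 3:
        kern = np.hanning(n_kern + 2)[1:-1]
        kern /= kern.sum()
        pad = n_kern // 2
        padded = np.pad(scale, pad, mode="edge")
        scale = signal.convolve(padded, kern, mode="valid")
    return carrier * scale


def _band_envelope(config: SimConfig, base_rms: float,
                   condition_rms: np.ndarray) -> np.ndarray:
    """Per-sample target RMS for one band on one channel.

    ``condition_rms`` gives the contraction-interval RMS per trial; rest
    intervals sit at the rest-fraction-attenuated level of the same trial,
    with linear ramps of ``ramp_s`` (up) and ``ramp_down_s`` (down).
    """
    fs = config.sampling_rate
    n_ramp = round(config.ramp_s * fs)
    n_down = round(config.ramp_down_s * fs)
    n_lead = round(config.lead_in_s * fs)
    rest_rms = base_rms * (condition_rms / base_rms) ** config.rest_fraction

    # piecewise-linear breakpoints: hold the previous trial's rest level up
    # to each onset, ramp up, plateau, ramp down, hold this trial's rest
    xs, ys = [0.0], [rest_rms[0]]
    for k in range(config.n_trials):
        s0 = n_lead + k * config.samples_per_trial
        s1 = s0 + config.contraction_samples
        prev_rest = rest_rms[k - 1] if k > 0 else rest_rms[0]
        xs += [s0, s0 + n_ramp, s1, s1 + n_down]
        ys += [prev_rest, condition_rms[k], condition_rms[k], rest_rms[k]]
    xs.append(float(config.n_samples - 1))
    ys.append(rest_rms[-1])
    return np.interp(np.arange(config.n_samples), xs, ys)


def simulate_subject(config: SimConfig, subject_index: int) -> Recording:
    """Generate one subject's continuous recording.

    Deterministic given ``(config.seed, subject_index)``: the subject's RNG
    stream is seeded with ``seed + subject_index``.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigurationError(
            f"subject_index {subject_index} outside [0, {config.n_subjects})"
        )
    increments = injected_increments_db(config, subject_index)
    rng = np.random.default_rng(config.seed + subject_index)
    # burn the jitter draws so signal noise is independent of them
    rng.normal(size=2 * len(config.band_effects))

    fs = config.sampling_rate
    n = config.n_samples
    t = np.arange(n) / fs
    data = np.empty((len(config.channel_labels), n))

    line_phase = rng.uniform(0, 2 * np.pi)
    cond_idx = np.array(
        [config.trial_condition_index(k) for k in range(config.n_trials)]
    )

    line = config.line_amp * np.sin(2 * np.pi * config.line_freq * t + line_phase)
    band_names = sorted(config.band_effects)

    # motor channels: independent, segment-calibrated carriers whose
    # amplitude steps with the subject's fatigue-condition increments
    for ch, label in enumerate(config.channel_labels):
        if label not in config.motor_channels:
            continue
        x = _pink_noise(rng, n, fs, config.noise_exponent, config.noise_rms)
        for name in band_names:
            band = config.band_effects[name]
            if band.base_rms == 0:
                continue
            pad_lo, pad_hi = config.carrier_pads(name)
            carrier = _normalise_carrier(
                *_band_carrier(rng, n, fs, band.low, band.high,
                               pad_lo=pad_lo, pad_hi=pad_hi),
                config,
            )
            inc = np.array([increments[name][c] for c in CONDITIONS])
            if config.effect_profile == "step":
                trial_db = inc[cond_idx]
            else:  # linear drift from Min to Sev increment
                frac = np.arange(config.n_trials) / max(1, config.n_trials - 1)
                trial_db = inc[0] + frac * (inc[2] - inc[0])
            condition_rms = band.base_rms * 10.0 ** (trial_db / 20.0)
            x += _band_envelope(config, band.base_rms, condition_rms) * carrier
        data[ch] = x + line

    # unrelated channels: a shared rhythm generator per band, projected
    # with alternating signs (dipole-like field), so the montage average
    # carries none of it and the common average reference stays clean of
    # unrelated-rhythm power; carriers are left un-calibrated so these
    # channels keep natural trial-to-trial spectral variability
    unrelated = [i for i, lab in enumerate(config.channel_labels)
                 if lab not in config.motor_channels]
    shared = {}
    for name in band_names:
        band = config.band_effects[name]
        if band.base_rms == 0:
            continue
        pad_lo, pad_hi = config.carrier_pads(name)
        carrier, nominal = _band_carrier(
            rng, n, fs, band.low, band.high, pad_lo=pad_lo, pad_hi=pad_hi
        )
        shared[name] = (band.base_rms * config.unrelated_amp_scale) * carrier
    for j, ch in enumerate(unrelated):
        x = _pink_noise(rng, n, fs, config.noise_exponent, config.noise_rms)
        sign = 1.0 if j % 2 == 0 else -1.0
        for osc in shared.values():
            x += sign * osc
        data[ch] = x + line

    return Recording(
        data=data,
        sampling_rate=fs,
        channel_labels=list(config.channel_labels),
        events=config.trial_events(),
        subject_id=f"S{subject_index:02d}",
    )


def simulate_cohort(config: SimConfig) -> list[Recording]:
    """One Recording per subject, each on its own deterministic sub-seed."""
    logger.info("simulating cohort: %d subjects, %d trials each",
                config.n_subjects, config.n_trials)
    return [simulate_subject(config, j) for j in range(config.n_subjects)]


def periodogram_band_power_db(rec: Recording, channel: str,
                              band: tuple[float, float],
                              windows: list[tuple[float, float]]) -> float:
    """Periodogram band power (dB re 1 uV^2/Hz) pooled over time windows.

    Independent spectral estimate used to verify injected effects: windows
    are (start_s, stop_s) spans of the continuous recording; a boxcar
    periodogram is computed per window, averaged across windows, then
    band-averaged and log-transformed.  The boxcar window makes the in-band
    power of a window equal its plain mean square (Parseval), so the
    estimate inherits the generator's per-segment calibration exactly.
    """
    fs = rec.sampling_rate
    ch = list(rec.channel_labels).index(channel)
    psds = []
    for t0, t1 in windows:
        seg = rec.data[ch, round(t0 * fs):round(t1 * fs)]
        f, pxx = signal.periodogram(seg, fs=fs, window="boxcar", detrend=False)
        psds.append(pxx)
    pxx = np.mean(psds, axis=0)
    sel = (f >= band[0]) & (f < band[1])
    return 10.0 * np.log10(np.mean(pxx[sel]))
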