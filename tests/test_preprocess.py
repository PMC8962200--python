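"""Filtering, re-referencing, epoching and condition-assignment checks."""

import logging

import numpy as np
import pytest

from fatiguersp import (
    Recording,
    assign_fatigue_conditions,
    epoch_offset_with_baseline_swap,
    epoch_onset,
    filter_recording,
    reject_noisy_epochs,
    rereference_car,
    select_condition_trials,
)
from fatiguersp.containers import (
    CONDITIONS,
    UNASSIGNED,
    ConfigurationError,
    EpochSet,
    StructureError,
)

FS = 250.0


def sine_recording(freqs_amps, duration=20.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    data = np.stack([a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps])
    return Recording(data=data, sampling_rate=fs,
                     channel_labels=[f"ch{i}" for i in range(len(freqs_amps))],
                     events=[])


def mid_rms(x, fs=FS, skip=5.0):
    """RMS away from filter edge transients."""
    n = int(skip * fs)
    return np.sqrt(np.mean(x[n:-n] ** 2))


class TestFiltering:
    def test_frequency_response_oracle(self):
        """Pass-band unity within 0.5 dB; 60 Hz notched below 0.1 uV;
        0.3 Hz drift attenuated by at least 20 dB."""
        rec = sine_recording([(10.0, 1.0), (60.0, 10.0), (0.3, 1.0)],
                             duration=40.0)
        out = filter_recording(rec, low=1.0, high=100.0, notch_base=60.0)
        gain_10 = 20 * np.log10(mid_rms(out.data[0]) / mid_rms(rec.data[0]))
        assert abs(gain_10) < 0.5
        residual_60 = mid_rms(out.data[1]) * np.sqrt(2)  # RMS -> amplitude
        assert residual_60 < 0.1
        gain_03 = 20 * np.log10(mid_rms(out.data[2]) / mid_rms(rec.data[2]))
        assert gain_03 < -20.0

    def test_cutoff_at_nyquist_rejected(self):
        rec = sine_recording([(10.0, 1.0)])
        with pytest.raises(ConfigurationError):
            filter_recording(rec, low=1.0, high=125.0)
        with pytest.raises(ConfigurationError):
            filter_recording(rec, low=50.0, high=10.0)

    def test_length_preserved(self, subject_recording):
        out = filter_recording(subject_recording)
        assert out.data.shape == subject_recording.data.shape

    def test_filter_and_car_commute(self):
        rng = np.random.default_rng(0)
        rec = Recording(data=rng.standard_normal((4, 5000)),
                        sampling_rate=FS, channel_labels=list("abcd"),
                        events=[])
        a = rereference_car(filter_recording(rec))
        b = filter_recording(rereference_car(rec))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)


class TestCommonAverageReference:
    def test_constant_channels_example(self):
        rec = Recording(data=np.array([[1.0] * 10, [2.0] * 10, [3.0] * 10]),
                        sampling_rate=FS, channel_labels=["a", "b", "c"],
                        events=[])
        out = rereference_car(rec)
        np.testing.assert_allclose(out.data[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(1)
        rec = Recording(data=rng.standard_normal((8, 1000)),
                        sampling_rate=FS,
                        channel_labels=[f"c{i}" for i in range(8)], events=[])
        once = rereference_car(rec)
        assert np.all(np.abs(once.data.mean(axis=0)) < 1e-10)
        twice = rereference_car(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_rejected(self):
        rec = Recording(data=np.zeros((1, 100)), sampling_rate=FS,
                        channel_labels=["a"], events=[])
        with pytest.raises(ConfigurationError):
            rereference_car(rec)


def ramp_recording(starts, n_samples, contraction_samples=1250, fs=FS):
    """Single-channel recording whose samples equal their own index."""
    data = np.arange(n_samples, dtype=float)[None, :]
    events = []
    for s in starts:
        events.append(("Start", s))
        events.append(("End", s + contraction_samples))
    return Recording(data=data, sampling_rate=fs, channel_labels=["c0"],
                     events=events)


class TestEpoching:
    def test_onset_epoch_sample_arithmetic(self):
        rec = ramp_recording([2500], 10000)
        epochs = epoch_onset(rec)
        assert epochs.data.shape == (1, 1, 1625)
        # samples 2125..3749 inclusive under the half-open convention
        np.testing.assert_array_equal(epochs.data[0, 0],
                                      np.arange(2125, 3750))
        assert epochs.t0_offset_s == -1.5

    def test_insufficient_history_drops_trial_with_warning(self, caplog):
        rec = ramp_recording([100, 2500], 10000)
        with caplog.at_level(logging.WARNING, logger="fatiguersp.preprocess"):
            epochs = epoch_onset(rec)
        assert epochs.n_trials == 1
        assert epochs.trial_order.tolist() == [1]
        assert any("dropping trial 0" in m for m in caplog.messages)

    def test_sixty_starts_give_sixty_ordered_epochs(self, subject_recording):
        epochs = epoch_onset(subject_recording)
        assert epochs.n_trials == 60
        assert epochs.trial_order.tolist() == list(range(60))

    def test_no_start_events_is_an_error(self):
        rec = Recording(data=np.zeros((1, 1000)), sampling_rate=FS,
                        channel_labels=["a"], events=[])
        with pytest.raises(StructureError):
            epoch_onset(rec)

    def test_offset_swap_is_bit_identical_to_pre_onset_baseline(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((2, 12000))
        events = [("Start", 2000), ("End", 3250), ("Start", 3750),
                  ("End", 5000)]
        rec = Recording(data=data, sampling_rate=FS,
                        channel_labels=["a", "b"], events=events)
        epochs = epoch_offset_with_baseline_swap(rec)
        assert epochs.data.shape[2] == 1500  # [-4, 2) s at 250 Hz
        for i, (start, end) in enumerate(rec.trial_pairs()):
            swapped = epochs.data[i, :, :375]
            baseline = data[:, start - 375:start]
            np.testing.assert_array_equal(swapped, baseline)
            # non-swapped content preserved from the continuous recording
            np.testing.assert_array_equal(
                epochs.data[i, :, 375:], data[:, end - 625:end + 500]
            )

    def test_offset_epoch_near_recording_end_dropped(self, caplog):
        rec = ramp_recording([2000], 3600)  # End at 3250, < 2 s tail
        with caplog.at_level(logging.WARNING, logger="fatiguersp.preprocess"):
            with pytest.raises(StructureError):
                epoch_offset_with_baseline_swap(rec)


def toy_epochs(n_trials, rejected=None):
    data = np.zeros((n_trials, 1, 10))
    return EpochSet(data=data, anchor="onset", t0_offset_s=-1.5,
                    sampling_rate=FS, channel_labels=["c0"],
                    trial_order=np.arange(n_trials),
                    rejected=rejected)


class TestRejection:
    def test_square_pulse_flags_only_that_trial(self):
        epochs = toy_epochs(12)
        epochs.data[7, 0, 3] = 500.0
        out = reject_noisy_epochs(epochs, peak_to_peak_limit=200.0)
        assert out.rejected.tolist() == [i == 7 for i in range(12)]

    def test_infinite_limit_rejects_nothing(self):
        epochs = toy_epochs(5)
        epochs.data += np.random.default_rng(0).standard_normal(
            epochs.data.shape) * 100
        out = reject_noisy_epochs(epochs, peak_to_peak_limit=np.inf)
        assert not out.rejected.any()

    def test_clean_synthetic_subject_rejection_below_5_percent(
            self, subject_recording):
        epochs = reject_noisy_epochs(epoch_onset(subject_recording),
                                     peak_to_peak_limit=200.0)
        assert epochs.rejected.mean() < 0.05

    def test_all_rejected_is_an_error(self):
        epochs = toy_epochs(3)
        epochs.data[:, 0, 0] = 1000.0
        with pytest.raises(StructureError):
            reject_noisy_epochs(epochs, peak_to_peak_limit=200.0)


class TestConditionAssignment:
    @pytest.mark.parametrize("n,expected_sizes,n_unassigned", [
        (90, (30, 30, 30), 0),
        (92, (30, 30, 30), 2),
        (7, (2, 2, 2), 1),
    ])
    def test_chronological_thirds(self, n, expected_sizes, n_unassigned):
        out = assign_fatigue_conditions(toy_epochs(n))
        sizes = tuple(int(np.sum(out.condition == c)) for c in CONDITIONS)
        assert sizes == expected_sizes
        assert int(np.sum(out.condition == UNASSIGNED)) == n_unassigned
        # the trailing remainder is what stays unassigned
        if n_unassigned:
            assert all(out.condition[-n_unassigned:] == UNASSIGNED)

    def test_rejected_trials_never_assigned(self):
        rejected = np.zeros(9, dtype=bool)
        rejected[[0, 4]] = True
        out = assign_fatigue_conditions(toy_epochs(9, rejected=rejected))
        assert all(out.condition[out.rejected] == UNASSIGNED)
        sizes = [int(np.sum(out.condition == c)) for c in CONDITIONS]
        assert sizes == [2, 2, 2]  # 7 retained -> thirds of 2

    def test_too_few_trials(self):
        with pytest.raises(StructureError):
            assign_fatigue_conditions(toy_epochs(2))

    def test_conditions_are_chronologically_ordered(self):
        out = select_condition_trials(
            assign_fatigue_conditions(toy_epochs(60)), fraction=0.10)
        maxima = [max(np.flatnonzero(out.condition == c), default=-1)
                  for c in CONDITIONS]
        minima = [min(np.flatnonzero(out.condition == c), default=10 ** 9)
                  for c in CONDITIONS]
        assert maxima[0] < minima[1] and maxima[1] < minima[2]


class TestTrialSelection:
    def test_ten_percent_of_80_trials_selects_8_per_condition(self):
        out = select_condition_trials(
            assign_fatigue_conditions(toy_epochs(80)), fraction=0.10)
        for c in CONDITIONS:
            assert int(np.sum(out.condition == c)) == 8

    def test_middle_selection_placement(self):
        # 78 trials -> sets of 26; n_sel = 8 -> within-set indices 9..16
        out = select_condition_trials(
            assign_fatigue_conditions(toy_epochs(78)), fraction=0.10)
        mod = np.flatnonzero(out.condition == "ModFatg")
        assert mod.tolist() == list(range(26 + 9, 26 + 17))

    def test_fraction_one_keeps_all_assigned(self):
        out = select_condition_trials(
            assign_fatigue_conditions(toy_epochs(60)), fraction=1.0)
        for c in CONDITIONS:
            assert int(np.sum(out.condition == c)) == 20

    def test_oversized_selection_rejected(self):
        epochs = assign_fatigue_conditions(toy_epochs(9))
        with pytest.raises(ConfigurationError):
            select_condition_trials(epochs, fraction=0.9)
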