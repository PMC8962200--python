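"""ERSP estimator family: identities, toy oracle, wavelet behaviour."""

import numpy as np
import pytest

from fatiguersp import (
    SimConfig,
    band_average,
    baseline_condition_summary,
    compute_common_baseline,
    compute_ers,
    compute_ersp,
    epoch_onset,
    ersp_analysis,
    preprocess_recording,
    simulate_subject,
    tf_decompose,
    time_average_ersp,
)
from fatiguersp.containers import (
    ConfigurationError,
    EpochSet,
    StructureError,
    TFPower,
)

DB_2X = 10 * np.log10(2.0)  # 3.010299956639812


def toy_tf():
    """2 trials x 3 frequencies x 4 times with hand-computable powers."""
    power = np.array([
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 2.0, 2.0, 2.0],
         [1.0, 1.0, 4.0, 4.0]],
        [[3.0, 2.0, 5.0, 4.0],
         [6.0, 2.0, 4.0, 4.0],
         [3.0, 1.0, 2.0, 2.0]],
    ])
    return TFPower(
        power=power, freqs=np.array([10.0, 20.0, 30.0]),
        times=np.array([0.0, 0.5, 1.0, 1.5]),
        condition=np.array(["MinFatg", "MinFatg"], dtype=object),
        channel="C3", anchor="onset",
    )


class TestToyOracle:
    """Every aggregation level against spreadsheet-style hand arithmetic."""

    def test_ers_is_trial_mean(self):
        ers = compute_ers(toy_tf(), "MinFatg")
        np.testing.assert_array_equal(ers, [[2, 2, 4, 4],
                                            [4, 2, 3, 3],
                                            [2, 1, 3, 3]])

    def test_common_baseline_pools_trials_and_times(self):
        base = compute_common_baseline(toy_tf(), (0.0, 1.0))
        np.testing.assert_allclose(base.b_avg, [2.0, 3.0, 1.5])
        assert base.p == 2
        assert base.q.tolist() == [2, 2, 2]

    def test_ersp_log_ratio_values(self):
        tf = toy_tf()
        base = compute_common_baseline(tf, (0.0, 1.0))
        ersp = compute_ersp(compute_ers(tf, "MinFatg"), base)
        expected = 10 * np.log10(np.array([
            [1.0, 1.0, 2.0, 2.0],
            [4 / 3, 2 / 3, 1.0, 1.0],
            [4 / 3, 2 / 3, 2.0, 2.0],
        ]))
        np.testing.assert_allclose(ersp, expected, atol=1e-12)

    def test_time_average_and_band_average(self):
        tf = toy_tf()
        base = compute_common_baseline(tf, (0.0, 1.0))
        ersp = compute_ersp(compute_ers(tf, "MinFatg"), base)
        vec = time_average_ersp(ersp, tf, (1.0, 2.0))
        np.testing.assert_allclose(vec, [DB_2X, 0.0, DB_2X], atol=1e-12)
        assert band_average(vec, tf.freqs, (5.0, 25.0)) == pytest.approx(
            DB_2X / 2, abs=1e-12)
        assert band_average(vec, tf.freqs, (0.0, 40.0)) == pytest.approx(
            2 * DB_2X / 3, abs=1e-12)

    def test_condition_baseline_equals_pooled_baseline_gives_zero(self):
        tf = toy_tf()
        base = compute_common_baseline(tf, (0.0, 1.0))
        value = baseline_condition_summary(tf, base, (5.0, 35.0), "MinFatg")
        assert value == pytest.approx(0.0, abs=1e-12)


class TestGainModelIdentities:
    def test_ers_equal_to_baseline_gives_zero_db(self):
        tf = toy_tf()
        base = compute_common_baseline(tf, (0.0, 1.0))
        ersp = compute_ersp(np.tile(base.b_avg[:, None], (1, 4)), base)
        np.testing.assert_allclose(ersp, 0.0, atol=1e-12)

    def test_power_doubling_gives_3db(self):
        tf = toy_tf()
        base = compute_common_baseline(tf, (0.0, 1.0))
        ersp = compute_ersp(2 * np.tile(base.b_avg[:, None], (1, 4)), base)
        np.testing.assert_allclose(ersp, DB_2X, atol=1e-12)

    def test_global_rescaling_leaves_ersp_unchanged(self):
        tf = toy_tf()
        base = compute_common_baseline(tf, (0.0, 1.0))
        a = compute_ersp(compute_ers(tf, "MinFatg"), base)
        scaled = TFPower(
            power=tf.power * 7.3, freqs=tf.freqs, times=tf.times,
            condition=tf.condition, channel=tf.channel, anchor=tf.anchor,
        )
        base_s = compute_common_baseline(scaled, (0.0, 1.0))
        b = compute_ersp(compute_ers(scaled, "MinFatg"), base_s)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_errors_on_degenerate_inputs(self):
        tf = toy_tf()
        base = compute_common_baseline(tf, (0.0, 1.0))
        with pytest.raises(StructureError):
            compute_ers(tf, "SevFatg")
        with pytest.raises(StructureError):
            compute_ersp(np.zeros((3, 4)), base)
        zero = TFPower(power=np.zeros_like(tf.power), freqs=tf.freqs,
                       times=tf.times, condition=tf.condition,
                       channel="C3", anchor="onset")
        with pytest.raises(StructureError):
            compute_common_baseline(zero, (0.0, 1.0))


class TestTimeAverage:
    def test_constant_single_point_and_linear_ramp(self):
        tf = toy_tf()
        const = np.full((3, 4), 1.7)
        np.testing.assert_allclose(
            time_average_ersp(const, tf, (0.0, 2.0)), 1.7)
        np.testing.assert_allclose(
            time_average_ersp(const, tf, (0.5, 1.0)), const[:, 1])
        ramp = np.tile(np.array([0.0, 1.0, 2.0, 3.0]), (3, 1))
        # mean of a linear ramp over the window equals its midpoint value
        np.testing.assert_allclose(
            time_average_ersp(ramp, tf, (0.0, 2.0)), (0.0 + 3.0) / 2)

    def test_empty_window_is_an_error(self):
        tf = toy_tf()
        with pytest.raises(StructureError):
            time_average_ersp(np.zeros((3, 4)), tf, (5.0, 6.0))


class TestBandAverage:
    def test_examples(self):
        freqs = np.array([8.0, 10.0, 12.0])
        assert band_average(np.array([1.0, 2.0, 3.0]), freqs, (8, 13)) == 2.0
        stack = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        np.testing.assert_allclose(
            band_average(stack, freqs, (8, 13)), [2.0, 5.0])
        np.testing.assert_allclose(
            band_average(stack[::-1], freqs, (8, 13)), [5.0, 2.0])
        with pytest.raises(ConfigurationError):
            band_average(stack, freqs, (50, 60))


class TestWaveletDecomposition:
    def test_zero_signal_gives_zero_power(self):
        epochs = EpochSet(
            data=np.zeros((2, 1, 1625)), anchor="onset", t0_offset_s=-1.5,
            sampling_rate=250.0, channel_labels=["C3"],
            trial_order=np.arange(2),
        )
        tf = tf_decompose(epochs, "C3", freqs=np.arange(8.0, 14.0))
        np.testing.assert_allclose(tf.power, 0.0, atol=1e-20)

    def test_amplitude_scaling_squares_power(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 1, 1625))
        mk = lambda c: EpochSet(  # noqa: E731
            data=c * data, anchor="onset", t0_offset_s=-1.5,
            sampling_rate=250.0, channel_labels=["C3"],
            trial_order=np.arange(2))
        a = tf_decompose(mk(1.0), "C3", freqs=np.arange(8.0, 14.0))
        b = tf_decompose(mk(3.0), "C3", freqs=np.arange(8.0, 14.0))
        np.testing.assert_allclose(b.power, 9.0 * a.power, rtol=1e-10)

    def test_narrowband_peak_matches_periodogram_oracle(self):
        from scipy.signal import periodogram

        fs = 250.0
        t = np.arange(1625) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        epochs = EpochSet(
            data=np.repeat(sig, 2, axis=0), anchor="onset", t0_offset_s=-1.5,
            sampling_rate=fs, channel_labels=["C3"], trial_order=np.arange(2))
        tf = tf_decompose(epochs, "C3", freqs=np.arange(3.0, 31.0))
        mean_over_time = np.array([
            tf.power[0, i, tf.valid[i]].mean() for i in range(len(tf.freqs))
        ])
        wavelet_peak = tf.freqs[np.argmax(mean_over_time)]
        f, pxx = periodogram(sig[0, 0], fs=fs)
        oracle_peak = f[np.argmax(pxx)]
        assert wavelet_peak == tf.freqs[np.argmin(np.abs(tf.freqs - oracle_peak))]

    def test_low_frequency_needs_long_enough_epoch(self):
        epochs = EpochSet(
            data=np.zeros((1, 1, 250)), anchor="onset", t0_offset_s=-0.5,
            sampling_rate=250.0, channel_labels=["C3"],
            trial_order=np.arange(1))
        with pytest.raises(ConfigurationError):
            tf_decompose(epochs, "C3", freqs=np.arange(3.0, 10.0))

    def test_edge_points_marked_invalid(self):
        epochs = EpochSet(
            data=np.zeros((1, 1, 1625)), anchor="onset", t0_offset_s=-1.5,
            sampling_rate=250.0, channel_labels=["C3"],
            trial_order=np.arange(1))
        tf = tf_decompose(epochs, "C3", freqs=np.arange(3.0, 31.0))
        assert not tf.valid[0, 0]          # epoch edge at the lowest freq
        assert tf.valid[:, len(tf.times) // 2].all()
        # higher frequencies have shorter wavelets, hence wider validity
        assert tf.valid.sum(axis=1)[-1] >= tf.valid.sum(axis=1)[0]


class TestBaselineStationarity:
    def test_halving_baseline_time_points_changes_b_avg_below_1pct(
            self, subject_recording):
        # fraction=1 pools all 60 trials for a tight stationarity check
        epochs = preprocess_recording(subject_recording, channels=["C3"],
                                      fraction=1.0)
        tf = tf_decompose(epochs, "C3", freqs=np.arange(8.0, 14.0))
        full = compute_common_baseline(tf, (-1.5, -0.5))
        sub = TFPower(
            power=tf.power[:, :, ::2], freqs=tf.freqs, times=tf.times[::2],
            condition=tf.condition, channel=tf.channel, anchor=tf.anchor,
            valid=tf.valid[:, ::2],
        )
        half = compute_common_baseline(sub, (-1.5, -0.5))
        ratio = half.b_avg / full.b_avg
        assert np.all(np.abs(ratio - 1.0) < 0.01)


class TestEndToEndRecovery:
    def test_subject_level_gain_invariance(self, small_config):
        """Multiplying a subject's whole recording by c leaves every ERSP
        output unchanged to 1e-9 dB (gain-model invariance)."""
        rec = simulate_subject(small_config, 0)
        scaled = rec.copy()
        scaled.data *= 3.7
        outs = []
        for r in (rec, scaled):
            epochs = preprocess_recording(r, channels=["C3"],
                                          peak_to_peak_limit=np.inf)
            tf = tf_decompose(epochs, "C3", freqs=np.arange(8.0, 14.0))
            outs.append(ersp_analysis(tf, "steady"))
        for cond in ("MinFatg", "ModFatg", "SevFatg"):
            np.testing.assert_allclose(
                outs[0].ersp_time_avg[cond], outs[1].ersp_time_avg[cond],
                atol=1e-9)
            for band in ("alpha",):
                assert outs[0].band_scalar[(cond, band)] == pytest.approx(
                    outs[1].band_scalar[(cond, band)], abs=1e-9)

    def test_rest_effect_orders_condition_baselines(self):
        """With the rest-interval fatigue effect enabled, the per-condition
        baseline summaries at a motor channel order Min < Mod < Sev."""
        config = SimConfig(n_subjects=6, between_subject_sd=0.0,
                           rest_fraction=0.5, seed=2)
        values = {c: [] for c in ("MinFatg", "ModFatg", "SevFatg")}
        for j in range(config.n_subjects):
            rec = simulate_subject(config, j)
            epochs = preprocess_recording(rec, channels=["C3"])
            tf = tf_decompose(epochs, "C3", freqs=np.arange(8.0, 14.0))
            res = ersp_analysis(tf, "steady")
            for c in values:
                values[c].append(res.baseline_scalar[(c, "alpha")])
        means = {c: np.mean(v) for c, v in values.items()}
        assert means["MinFatg"] < means["ModFatg"] < means["SevFatg"]


class TestBaselineOptions:
    def test_min_fatigue_only_baseline_pools_fewer_trials(self):
        tf = toy_tf()
        tf.condition[1] = "SevFatg"
        pooled = compute_common_baseline(tf, (0.0, 1.0))
        min_only = compute_common_baseline(tf, (0.0, 1.0),
                                           conditions=("MinFatg",))
        assert pooled.p == 2 and min_only.p == 1
        # trial 0 baseline means per frequency: rows of its first 2 columns
        np.testing.assert_allclose(min_only.b_avg, [1.5, 2.0, 1.0])
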