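import numpy as np
import pytest

from oscimap import preprocess, synth


def _rec(data, rate=500.0, layout=None, bad=()):
    return synth.EEGRecording(
        data=np.asarray(data, dtype=float), rate=rate, layout=layout,
        subject_id="sub-t", cohort="HC", bad_channels=tuple(bad),
    )


class TestMeanCenter:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
            ([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0]),
        ],
    )
    def test_examples(self, row, expected, layout):
        rec = _rec(np.tile(row, (64, 1)), layout=layout)
        out = preprocess.mean_center(rec)
        np.testing.assert_allclose(out.data, np.tile(expected, (64, 1)), atol=1e-12)

    def test_random_channel_zero_mean(self, layout):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((64, 1000)) * 10, layout=layout)
        out = preprocess.mean_center(rec)
        tol = 1e-10 * out.data.std(axis=1)
        assert np.all(np.abs(out.data.mean(axis=1)) < np.maximum(tol, 1e-12))

    def test_nonfinite_rejected(self, layout):
        data = np.zeros((64, 10))
        data[3, 4] = np.nan
        with pytest.raises(ValueError):
            preprocess.mean_center(_rec(data, layout=layout))


class TestLineNoise:
    def _tone(self, freq, rate=500.0, dur=10.0):
        t = np.arange(int(rate * dur)) / rate
        return np.tile(np.sin(2 * np.pi * freq * t), (64, 1))

    def test_60hz_tone_strongly_attenuated(self, layout):
        rec = _rec(self._tone(60.0), layout=layout)
        out = preprocess.remove_line_noise(rec)
        assert out.data.std() < 0.1 * rec.data.std()

    @pytest.mark.parametrize("freq", [10.0, 55.0, 65.0])
    def test_passband_preserved(self, freq, layout):
        rec = _rec(self._tone(freq), layout=layout)
        out = preprocess.remove_line_noise(rec)
        mid = slice(1000, -1000)  # ignore filter edge transients
        ratio = out.data[:, mid].std() / rec.data[:, mid].std()
        assert abs(ratio - 1.0) < 0.02 if freq == 10.0 else ratio > 10 ** (-1 / 20)

    def test_zero_signal_stays_zero(self, layout):
        rec = _rec(np.zeros((64, 5000)), layout=layout)
        out = preprocess.remove_line_noise(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_line_freq_above_nyquist_rejected(self, layout):
        rec = _rec(np.zeros((64, 5000)), rate=100.0, layout=layout)
        with pytest.raises(ValueError):
            preprocess.remove_line_noise(rec, line_hz=60.0)


class TestAverageReference:
    def test_two_channel_definition(self, layout):
        rec = _rec(np.array([[1.0, 4.0], [3.0, 0.0]]), layout=layout)
        out = preprocess.average_reference(rec)
        np.testing.assert_allclose(out.data, [[-1.0, 2.0], [1.0, -2.0]])

    def test_idempotent(self, layout):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((64, 500)), layout=layout)
        once = preprocess.average_reference(rec)
        twice = preprocess.average_reference(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_column_means_vanish(self, layout):
        rng = np.random.default_rng(2)
        rec = _rec(rng.standard_normal((64, 500)) * 20, layout=layout)
        out = preprocess.average_reference(rec)
        assert np.all(np.abs(out.data.mean(axis=0)) < 1e-10 * out.data.std())

    def test_single_channel_rejected(self, layout):
        with pytest.raises(ValueError):
            preprocess.average_reference(_rec(np.zeros((1, 100)), layout=layout))


class TestFlagArtifacts:
    def test_clean_signal_no_flags(self, layout):
        rng = np.random.default_rng(3)
        rec = _rec(rng.standard_normal((64, 5000)) * 10, layout=layout)
        assert preprocess.flag_artifacts(rec, threshold=100.0) == []

    def test_single_spike_yields_one_interval(self, layout):
        data = np.random.default_rng(4).standard_normal((64, 10_000)) * 5
        spike_sample = 5000  # t = 10 s at 500 Hz
        data[10, spike_sample] = 500.0
        rec = _rec(data, layout=layout)
        flags = preprocess.flag_artifacts(rec, threshold=100.0)
        assert len(flags) == 1
        s, e = flags[0]
        assert s <= spike_sample < e

    def test_matches_bruteforce_scan(self, layout):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((64, 4000)) * 40
        rec = _rec(data, layout=layout)
        flags = preprocess.flag_artifacts(rec, threshold=100.0, margin_s=0.1)
        over = np.any(np.abs(data) > 100.0, axis=0)
        covered = np.zeros(4000, dtype=bool)
        for s, e in flags:
            covered[s:e] = True
        pad = int(0.1 * rec.rate)
        for i in np.flatnonzero(over):
            assert covered[max(0, i - pad) : i + pad].all()
        # flags only occur near an exceedance
        for s, e in flags:
            assert over[max(0, s - 1) : e + 1].any()

    def test_threshold_below_floor_flags_everything(self, layout):
        rec = _rec(np.full((64, 1000), 5.0), layout=layout)
        flags = preprocess.flag_artifacts(rec, threshold=1.0)
        assert flags == [(0, 1000)]


class TestEpochAndReject:
    def test_clean_two_minutes_gives_120_trials(self, layout):
        rec = _rec(np.zeros((64, 120 * 100)), rate=100.0, layout=layout)
        ts = preprocess.epoch_and_reject(rec, [])
        assert ts.trials.shape == (120, 64, 100)
        assert ts.n_kept == 120

    def test_flag_inside_one_trial_drops_it(self, layout):
        rec = _rec(np.zeros((64, 120 * 100)), rate=100.0, layout=layout)
        ts = preprocess.epoch_and_reject(rec, [(720, 730)])  # inside trial 7
        assert ts.n_kept == 119
        assert not ts.kept_mask[7]

    def test_flag_straddling_two_trials_drops_both(self, layout):
        rec = _rec(np.zeros((64, 1000)), rate=100.0, layout=layout)
        ts = preprocess.epoch_and_reject(rec, [(195, 205)])
        assert not ts.kept_mask[1] and not ts.kept_mask[2]
        assert ts.n_kept == 8

    def test_subsecond_recording_gives_zero_trials(self, layout):
        rec = _rec(np.zeros((64, 50)), rate=100.0, layout=layout)
        ts = preprocess.epoch_and_reject(rec, [])
        assert ts.trials.shape[0] == 0


class TestInterpolation:
    def test_constant_neighbours_give_constant(self, layout):
        trials = np.random.default_rng(6).standard_normal((3, 64, 100))
        bad = "Cz"
        bi = layout.index(bad)
        # set every other channel to constant 2 uV
        trials[:, np.arange(64) != bi, :] = 2.0
        ts = preprocess.TrialSet(trials, 100.0, layout, np.ones(3, bool), "s", "HC")
        out = preprocess.interpolate_bad_channels(ts, [bad], k=4)
        np.testing.assert_allclose(out.trials[:, bi, :], 2.0)
        assert out.interpolated_channels == (bad,)

    def test_matches_bruteforce_nearest_mean(self, layout):
        rng = np.random.default_rng(7)
        trials = rng.standard_normal((2, 64, 50))
        bad = "PO3"
        bi = layout.index(bad)
        ts = preprocess.TrialSet(trials.copy(), 100.0, layout, np.ones(2, bool), "s", "HC")
        out = preprocess.interpolate_bad_channels(ts, [bad], k=4)
        good = [i for i in range(64) if i != bi]
        d = [np.linalg.norm(layout.positions3d[g] - layout.positions3d[bi]) for g in good]
        nearest = [good[i] for i in np.argsort(d)[:4]]
        expected = trials[:, nearest, :].mean(axis=1)
        np.testing.assert_allclose(out.trials[:, bi, :], expected, atol=1e-12)

    def test_empty_bad_list_is_identity(self, layout):
        trials = np.random.default_rng(8).standard_normal((2, 64, 50))
        ts = preprocess.TrialSet(trials.copy(), 100.0, layout, np.ones(2, bool), "s", "HC")
        out = preprocess.interpolate_bad_channels(ts, [])
        np.testing.assert_array_equal(out.trials, trials)

    def test_all_channels_bad_rejected(self, layout):
        trials = np.zeros((1, 64, 10))
        ts = preprocess.TrialSet(trials, 100.0, layout, np.ones(1, bool), "s", "HC")
        with pytest.raises(ValueError):
            preprocess.interpolate_bad_channels(ts, list(layout.names))


class TestTemporalDerivative:
    def _ts(self, trials, rate, layout):
        return preprocess.TrialSet(np.asarray(trials, float), rate, layout,
                                   np.ones(len(trials), bool), "s", "HC")

    def test_constant_trial_becomes_zero(self, layout):
        out = preprocess.temporal_derivative(self._ts(np.full((1, 64, 100), 3.0), 100, layout))
        np.testing.assert_allclose(out.trials, 0.0)
        assert out.trials.shape[-1] == 99

    def test_sinusoid_amplitude_closed_form(self, layout):
        rate, f = 500.0, 10.0
        t = np.arange(int(rate)) / rate
        trial = np.tile(np.sin(2 * np.pi * f * t), (64, 1))[None]
        out = preprocess.temporal_derivative(self._ts(trial, rate, layout))
        expected = 2.0 * np.sin(np.pi * f / rate)  # first difference of a sinusoid
        amp = (out.trials.max() - out.trials.min()) / 2.0
        assert abs(amp - expected) / expected < 0.01

    def test_linear_ramp_becomes_constant(self, layout):
        m = 0.25
        trial = np.tile(m * np.arange(100.0), (64, 1))[None]
        out = preprocess.temporal_derivative(self._ts(trial, 100, layout))
        np.testing.assert_allclose(out.trials, m, atol=1e-12)

    def test_derivative_attenuates_low_frequencies(self, layout):
        from scipy import signal as sps

        rng = np.random.default_rng(9)
        x = rng.standard_normal(50_000)
        y = np.diff(x)
        f, pin = sps.welch(x, fs=500.0, nperseg=4096)
        _, pout = sps.welch(y, fs=500.0, nperseg=4096)
        ratio = pout[: len(pin)] / pin
        r2 = ratio[np.argmin(np.abs(f - 2.0))]
        r40 = ratio[np.argmin(np.abs(f - 40.0))]
        assert r2 < r40


class TestPipeline:
    def test_full_pipeline_contract(self, short_recording):
        ts = preprocess.run_pipeline(short_recording)
        assert ts.differenced
        assert ts.trials.shape[1] == 64
        assert ts.trials.shape[2] == int(short_recording.rate) - 1
        assert ts.trials.shape[0] == int(short_recording.duration_s)
        assert ts.n_kept <= ts.trials.shape[0]

    def test_rejection_monotone_in_threshold(self, short_recording):
        from dataclasses import replace

        loose = preprocess.run_pipeline(
            short_recording, preprocess.PreprocessParams(artifact_threshold=100.0))
        strict = preprocess.run_pipeline(
            short_recording, preprocess.PreprocessParams(artifact_threshold=50.0))
        # lowering the threshold can only reject more trials
        assert np.all(loose.kept_mask | ~strict.kept_mask)

    def test_ground_truth_bad_channels_are_interpolated(self, layout):
        cfg = synth.SimulationConfig(duration_s=5.0, bad_channel_rate=0.2)
        rec = synth.generate_recording(
            synth.CohortSignature("HC", ()), cfg, seed=123, layout=layout)
        assert rec.bad_channels  # the seed produces at least one bad contact
        ts = preprocess.run_pipeline(rec)
        assert set(ts.interpolated_channels) == set(rec.bad_channels)
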