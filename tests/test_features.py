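"""Feature pipeline: filtering, epoching, ERD/ERSP, MRCP, band power."""

import numpy as np
import pytest

from mieeg.features import (ALPHA_BAND, BETA_BAND, Epochs, TimeFrequencyMap,
                            bandpass_butterworth, baseline_power,
                            characteristic_frequency, epoch_signal,
                            erd_onset, erd_peak, erd_percent, feature_row,
                            feature_table, frequency_power_curve,
                            mean_power, mrcp_extract, stft_ersp)
from mieeg.timeseries import TimeSeries

FS = 1000.0


def tone_epochs(freq=10.0, n_trials=20, amplitude=None, seed=0,
                window=(-5.0, 2.0), noise=0.0):
    """Random-phase tone trials with an optional amplitude envelope."""
    rng = np.random.default_rng(seed)
    t = np.arange(window[0], window[1], 1 / FS)
    env = np.ones_like(t) if amplitude is None else amplitude(t)
    data = np.stack([
        env * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        + noise * rng.standard_normal(t.size)
        for _ in range(n_trials)
    ])
    return Epochs(data, FS, window=window)


class TestBandpass:
    def mid_amplitude(self, ts):
        mid = ts.samples[len(ts) // 4: -len(ts) // 4]
        return (mid.max() - mid.min()) / 2

    def test_passband_gain(self):
        t = np.arange(0, 10, 1 / FS)
        ts = TimeSeries(np.sin(2 * np.pi * 10 * t), FS)
        out = bandpass_butterworth(ts, 8.0, 30.0)
        assert self.mid_amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_stopband_rejection(self):
        t = np.arange(0, 10, 1 / FS)
        ts = TimeSeries(np.sin(2 * np.pi * 2 * t), FS)
        out = bandpass_butterworth(ts, 8.0, 30.0)
        assert self.mid_amplitude(out) < 0.1

    def test_low_frequency_band_for_mrcp(self):
        # long signal: the 0.1 Hz corner has a seconds-long edge transient
        t = np.arange(0, 60, 1 / FS)
        ts = TimeSeries(np.sin(2 * np.pi * 5 * t), FS)
        out = bandpass_butterworth(ts, 0.1, 10.0)
        assert self.mid_amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_invalid_band(self):
        ts = TimeSeries(np.zeros(100), FS)
        with pytest.raises(ValueError):
            bandpass_butterworth(ts, 30.0, 8.0)
        with pytest.raises(ValueError):
            bandpass_butterworth(ts, 8.0, 600.0)


class TestEpoching:
    def test_sample_counts(self):
        ts = TimeSeries(np.arange(20_000, dtype=float), FS, t0=0.0)
        ep = epoch_signal(ts, onsets=[5.0], window=(-1.0, 1.0))
        assert ep.data.shape == (1, 2000)
        ep = epoch_signal(ts, onsets=[6.0, 12.0], window=(-5.0, 2.0))
        assert ep.data.shape == (2, 7000)

    def test_onset_column_is_t_zero(self):
        ts = TimeSeries(np.arange(5000, dtype=float), FS, t0=0.0)
        ep = epoch_signal(ts, onsets=[2.0], window=(-1.0, 1.0))
        onset_col = np.argmin(np.abs(ep.times))
        assert ep.data[0, onset_col] == 2000.0

    def test_out_of_range_onset_names_trial(self):
        ts = TimeSeries(np.zeros(3000), FS, t0=0.0)
        with pytest.raises(ValueError, match="trial 1"):
            epoch_signal(ts, onsets=[2.0, 0.5], window=(-1.0, 1.0))

    def test_invalid_window_geometry(self):
        with pytest.raises(ValueError):
            Epochs(np.zeros((2, 3000)), FS, window=(0.5, 3.5),
                   baseline=(0.5, 1.0))


class TestErdPercent:
    def test_identities(self):
        assert erd_percent(1.0, [1.0]) == 0.0
        assert erd_percent(0.5, [1.0]) == -50.0
        assert erd_percent(2.0, [1.0]) == 100.0

    def test_matches_brute_force_loop(self, rng):
        """Mean-square epochs and the m-epoch baseline agree with an
        explicit sample-by-sample loop."""
        epochs = rng.normal(0, 2, size=(6, 500))
        baseline = rng.normal(0, 2, size=(4, 500))
        slow = []
        eb_terms = []
        for row in baseline:
            eb_terms.append(sum(x * x for x in row) / row.size)
        eb = sum(eb_terms) / len(eb_terms)
        for row in epochs:
            e = sum(x * x for x in row) / row.size
            slow.append((e - eb) / eb * 100.0)
        fast = erd_percent(mean_power(epochs), mean_power(baseline))
        np.testing.assert_allclose(fast, slow, rtol=1e-12)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            erd_percent(1.0, [0.0])


class TestStftErsp:
    def test_white_noise_self_baseline(self, rng):
        ep = Epochs(rng.standard_normal((50, 7000)), FS)
        tf = stft_ersp(ep)
        base = tf.values[:, (tf.times >= -5) & (tf.times <= -2)]
        assert abs(base.mean()) < 0.5

    def test_half_amplitude_tone_drop(self):
        """Amplitude halving at onset = -6.02 dB power drop at the tone."""
        ep = tone_epochs(amplitude=lambda t: np.where(t < 0, 1.0, 0.5))
        tf = stft_ersp(ep)
        post = tf.values[tf.freqs == 10.0, :][0][tf.times >= 0.75]
        assert post.mean() == pytest.approx(-6.02, abs=1.0)

    def test_scale_invariance(self, rng):
        data = rng.standard_normal((10, 7000))
        a = stft_ersp(Epochs(data, FS))
        b = stft_ersp(Epochs(10.0 * data, FS))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_baseline_needs_one_frame(self):
        ep = Epochs(np.random.default_rng(0).standard_normal((2, 3000)),
                    FS, window=(-1.0, 2.0), baseline=(-1.0, -0.8))
        with pytest.raises(ValueError, match="baseline"):
            stft_ersp(ep)


def constant_map(value=0.0, fmax=40.0):
    times = np.arange(-4.5, 2.0, 0.05)
    freqs = np.arange(0.0, fmax + 1)
    return TimeFrequencyMap(times, freqs,
                            np.full((freqs.size, times.size), value))


class TestOnsetAndPeak:
    def test_onset_missing_when_above_threshold(self):
        assert erd_onset(constant_map(0.0)) is None

    def test_onset_single_cell(self):
        tf = constant_map(0.0)
        ti = np.argmin(np.abs(tf.times + 1.5))
        fi = np.argmin(np.abs(tf.freqs - 10.0))
        tf.values[fi, ti] = -25.0
        assert erd_onset(tf) == pytest.approx(-1.5, abs=1e-9)

    def test_peak_trivia(self):
        tf = constant_map(0.0)
        assert erd_peak(tf) == 0.0
        tf.values[10, 90] = -30.0  # 10 Hz, t = 0: inside band and window
        assert erd_peak(tf) == -30.0

    @pytest.mark.parametrize("residual", [0.05, 0.01])
    def test_planted_suppression_recovered(self, residual):
        """Onset of a tone suppression lands within one hop of the truth
        and the peak matches 20*log10(residual)."""
        ep = tone_epochs(
            amplitude=lambda t: np.where(t < -1.5, 1.0, residual))
        tf = stft_ersp(ep, window_length=0.1, hop=0.05)
        onset = erd_onset(tf)
        assert onset is not None
        assert abs(onset - (-1.5)) <= 0.05 + 1e-9
        assert erd_peak(tf) == pytest.approx(20 * np.log10(residual),
                                             abs=1.0)

    def test_onset_monotone_in_suppression_depth(self):
        """Deepening the suppression never delays the detected onset."""
        onsets = []
        for residual in (0.5, 0.12, 0.05, 0.01):
            ep = tone_epochs(
                amplitude=lambda t: np.where(t < -1.0, 1.0, residual))
            tf = stft_ersp(ep, window_length=0.1, hop=0.05)
            onset = erd_onset(tf)
            onsets.append(np.inf if onset is None else onset)
        assert all(a >= b - 1e-9 for a, b in zip(onsets, onsets[1:]))


class TestSpectralCurve:
    def test_constant_map(self):
        freqs, curve = frequency_power_curve(constant_map(-3.0))
        np.testing.assert_allclose(curve, -3.0)

    def test_minimum_at_suppressed_frequency(self):
        tf = constant_map(0.0)
        fi = np.argmin(np.abs(tf.freqs - 21.0))
        tf.values[fi, tf.times >= -2.0] = -5.0
        freqs, curve = frequency_power_curve(tf)
        assert freqs[np.argmin(curve)] == 21.0
        assert characteristic_frequency(freqs, curve, BETA_BAND) == 21.0

    def test_tone_drop_curve_minimum(self):
        ep = tone_epochs(freq=11.0,
                         amplitude=lambda t: np.where(t < 0, 1.0, 0.1),
                         noise=0.2)
        freqs, curve = frequency_power_curve(stft_ersp(ep))
        assert characteristic_frequency(freqs, curve, ALPHA_BAND) \
            == pytest.approx(11.0, abs=1.0)

    @pytest.mark.parametrize("band", [ALPHA_BAND, BETA_BAND])
    def test_characteristic_frequency_stays_in_band(self, band, rng):
        freqs = np.arange(0.0, 45.0)
        for _ in range(20):
            f = characteristic_frequency(freqs, rng.normal(size=freqs.size),
                                         band)
            assert band[0] <= f <= band[1]

    def test_monotone_curve_hits_band_edge(self):
        freqs = np.arange(0.0, 45.0)
        assert characteristic_frequency(freqs, freqs * 1.0, ALPHA_BAND) \
            == ALPHA_BAND[0]
        assert characteristic_frequency(freqs, -freqs * 1.0, ALPHA_BAND) \
            == ALPHA_BAND[1]

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            characteristic_frequency(np.arange(0, 5.0), np.zeros(5),
                                     (8.0, 13.0))


class TestMrcp:
    def test_all_zero_trials(self):
        ep = Epochs(np.zeros((3, 7000)), FS)
        _, peak, peak_time = mrcp_extract(ep)
        assert peak == 0.0
        assert peak_time == -3.0  # documented tie rule: first sample

    def test_planted_bump_peak_time(self, rng):
        t = np.arange(-5.0, 2.0, 1 / FS)
        bump = -8.0 * np.exp(-((t + 0.1) ** 2) / (2 * 0.3**2))
        data = np.stack([bump + 0.5 * rng.standard_normal(t.size)
                         for _ in range(30)])
        _, peak, peak_time = mrcp_extract(Epochs(data, FS))
        assert peak < -5.0
        assert peak_time == pytest.approx(-0.1, abs=0.05)

    def test_linearity_in_ensemble(self, rng):
        data = rng.standard_normal((8, 7000))
        _, p1, _ = mrcp_extract(Epochs(data, FS))
        _, p3, _ = mrcp_extract(Epochs(3.0 * data, FS))
        assert p3 == pytest.approx(3.0 * p1, rel=1e-9)


class TestBaselinePower:
    def test_zero_signal(self):
        assert baseline_power(Epochs(np.zeros((2, 7000)), FS)) == 0.0

    def test_unit_tone_half_power_and_quadratic_scaling(self):
        ep = tone_epochs(freq=10.0, n_trials=4)
        p1 = baseline_power(ep)
        assert p1 == pytest.approx(0.5, rel=0.05)
        ep2 = Epochs(2.0 * ep.data, FS)
        assert baseline_power(ep2) == pytest.approx(4.0 * p1, rel=1e-9)


class TestFeatureTable:
    def test_row_fields_and_band_limits(self, rng):
        ep = tone_epochs(freq=10.0,
                         amplitude=lambda t: np.where(t < 0, 1.0, 0.3),
                         noise=0.3)
        row = feature_row(ep)
        assert ALPHA_BAND[0] <= row["char_freq_alpha"] <= ALPHA_BAND[1]
        assert BETA_BAND[0] <= row["char_freq_beta"] <= BETA_BAND[1]
        assert row["erd_peak"] <= 0
        assert row["baseline_power"] > 0
        df = feature_table({"a": ep})
        assert list(df.index) == ["a"]
        assert "mrcp_peak" in df.columns
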