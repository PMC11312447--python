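import numpy as np
import pytest
from scipy import signal
from scipy.interpolate import PchipInterpolator

from cofluct.physio import (
    BeatSeries,
    RawPhysioSignal,
    alpha_power,
    default_wavelet_freqs,
    detect_ppg_peaks,
    eeg_wavelet_power,
    heart_rate,
    interpolate_blinks,
    ppg_amplitude,
    respiratory_volume,
    standardize_feature,
    tonic_skin_conductance,
)

FS = 100.0


def _sig(samples, modality, fs=FS):
    return RawPhysioSignal(samples=samples, fs_hz=fs, modality=modality)


class TestPeakDetection:
    def test_periodic_pulse_train(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.exp(-0.5 * (((t % 1.0) - 0.3) / 0.05) ** 2)
        beats = detect_ppg_peaks(_sig(x, "ppg"))
        assert abs(beats.peak_times_s.size - 60) <= 1
        spacing = np.diff(beats.peak_times_s)
        np.testing.assert_allclose(spacing, 1.0, atol=0.02)

    def test_synthetic_recall(self, physio_session):
        signals, truth = physio_session
        beats = detect_ppg_peaks(RawPhysioSignal(**signals["ppg"]))
        d = np.abs(truth.beat_times_s[:, None]
                   - beats.peak_times_s[None, :]).min(axis=1)
        assert (d < 0.05).mean() >= 0.99

    def test_constant_signal_errors(self):
        with pytest.raises(ValueError, match="constant|no peaks"):
            detect_ppg_peaks(_sig(np.ones(int(10 * FS)), "ppg"))

    def test_short_signal_errors(self):
        with pytest.raises(ValueError, match="5 s"):
            detect_ppg_peaks(_sig(np.random.default_rng(0).normal(size=100), "ppg"))

    def test_wrong_modality_errors(self):
        with pytest.raises(ValueError):
            detect_ppg_peaks(_sig(np.zeros(1000), "respiration"))


class TestBeatInterpolation:
    def test_constant_ibi_heart_rate(self):
        beats = BeatSeries(peak_times_s=np.arange(60.0),
                           peak_amplitudes=np.ones(60))
        hr = heart_rate(beats, FS, int(60 * FS))
        np.testing.assert_allclose(hr, 60.0, atol=0.1)

    def test_alternating_ibi_matches_pchip_oracle(self):
        # independent monotone-cubic evaluation at probe times
        times = np.cumsum(np.concatenate([[0.0], np.tile([0.8, 1.0], 15)]))
        beats = BeatSeries(peak_times_s=times, peak_amplitudes=np.ones(times.size))
        rate = 60.0 / np.diff(times)
        anchors = np.concatenate([[rate[0]], rate])
        oracle = PchipInterpolator(times, anchors)
        hr = heart_rate(beats, FS, int(times[-1] * FS))
        probes = np.linspace(times[0] + 0.5, times[-1] - 0.5, 10)
        idx = np.round(probes * FS).astype(int)
        np.testing.assert_allclose(hr[idx], oracle(idx / FS), atol=1e-8)

    def test_single_beat_errors(self):
        beats = BeatSeries(peak_times_s=[1.0], peak_amplitudes=[1.0])
        with pytest.raises(ValueError):
            heart_rate(beats, FS, 1000)

    def test_anchor_passthrough(self):
        # interpolation passes exactly through per-beat anchors
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 30, 20))
        amps = rng.uniform(1, 3, 20)
        beats = BeatSeries(peak_times_s=times, peak_amplitudes=amps)
        amp = ppg_amplitude(beats, 1000.0, 30001)
        idx = np.round(times * 1000).astype(int)
        np.testing.assert_allclose(amp[idx], amps, atol=5e-3)

    def test_constant_amplitude(self):
        beats = BeatSeries(peak_times_s=np.arange(30.0),
                           peak_amplitudes=np.full(30, 2.0))
        amp = ppg_amplitude(beats, FS, int(30 * FS))
        np.testing.assert_allclose(amp, 2.0, atol=1e-10)

    def test_linear_amplitudes_match_oracle(self):
        times = np.arange(40.0)
        amps = 1.0 + 0.05 * times
        beats = BeatSeries(peak_times_s=times, peak_amplitudes=amps)
        amp = ppg_amplitude(beats, FS, int(40 * FS))
        oracle = PchipInterpolator(times, amps)
        probes = np.linspace(1.0, 38.5, 10)
        idx = np.round(probes * FS).astype(int)
        np.testing.assert_allclose(amp[idx], oracle(idx / FS), atol=1e-8)

    def test_empty_beats_error(self):
        with pytest.raises(ValueError):
            ppg_amplitude(BeatSeries(peak_times_s=[], peak_amplitudes=[]), FS, 100)


class TestRespiratoryVolume:
    def test_pure_tone_analytic_value(self):
        t = np.arange(0, 300, 1 / FS)
        x = np.sin(2 * np.pi * 0.25 * t)
        rv = respiratory_volume(_sig(x, "respiration"))
        interior = rv[int(0.1 * rv.size):int(0.9 * rv.size)]
        np.testing.assert_allclose(interior, 2 * np.pi * 0.25, rtol=0.05)

    def test_chirp_tracks_rate_times_depth(self):
        # analytic instantaneous rate/depth oracle
        t = np.arange(0, 300, 1 / FS)
        f_t = 0.15 + (0.35 - 0.15) * t / t[-1]
        a_t = 1.0 + t / t[-1]
        phase = 2 * np.pi * np.cumsum(f_t) / FS
        x = a_t * np.sin(phase)
        rv = respiratory_volume(_sig(x, "respiration"))
        target = 2 * np.pi * f_t * a_t
        sl = slice(int(0.1 * rv.size), int(0.9 * rv.size))
        r = np.corrcoef(rv[sl], target[sl])[0, 1]
        assert r > 0.95

    def test_zero_signal_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            respiratory_volume(_sig(np.zeros(int(30 * FS)), "respiration"))


class TestTonicSkinConductance:
    def test_passband_tone_preserved_zero_phase(self):
        t = np.arange(0, 400, 1 / 10.0)
        x = np.sin(2 * np.pi * 0.05 * t)
        y = tonic_skin_conductance(
            RawPhysioSignal(samples=x, fs_hz=10.0, modality="skin_conductance"))
        sl = slice(400, -400)
        amp = np.sqrt(2) * y[sl].std()
        assert abs(amp - 1.0) < 0.05
        # zero-phase: peak cross-correlation at lag 0
        xs, ys = x[sl] - x[sl].mean(), y[sl] - y[sl].mean()
        xc = signal.correlate(ys, xs, mode="same")
        assert abs(np.argmax(xc) - xs.size // 2) <= 1

    def test_stopband_tone_attenuated(self):
        # filter-response oracle from the designed transfer function
        fs = 10.0
        sos = signal.butter(5, (0.01, 0.1), btype="bandpass", fs=fs, output="sos")
        w, h = signal.sosfreqz(sos, worN=[0.5], fs=fs)
        expected_gain = np.abs(h[0]) ** 2  # forward-backward pass
        assert expected_gain < 0.05
        t = np.arange(0, 400, 1 / fs)
        x = np.sin(2 * np.pi * 0.5 * t)
        y = tonic_skin_conductance(
            RawPhysioSignal(samples=x, fs_hz=fs, modality="skin_conductance"))
        amp = np.abs(y[200:-200]).max()
        assert amp < 0.05

    def test_dc_rejected(self):
        x = np.full(int(400 * 10), 10.0) + 0.01 * np.sin(
            2 * np.pi * 0.05 * np.arange(4000) / 10)
        y = tonic_skin_conductance(
            RawPhysioSignal(samples=x, fs_hz=10.0, modality="skin_conductance"))
        assert abs(y.mean()) < 1e-3  # DC of 10 suppressed by > 4 orders

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="two cycles"):
            tonic_skin_conductance(RawPhysioSignal(
                samples=np.zeros(100), fs_hz=10.0, modality="skin_conductance"))


class TestWaveletPower:
    def test_tone_selectivity(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        power, freqs = eeg_wavelet_power(_sig(x, "eeg_channel"))
        p = power[500:-500].mean(axis=0)
        i10 = np.argmin(np.abs(freqs - 10.0))
        i2 = np.argmin(np.abs(freqs - 2.0))
        assert p[i10] >= 20 * p[i2]

    def test_default_grid_spans_2_to_20(self):
        freqs = default_wavelet_freqs()
        assert freqs[0] == 2.0 and freqs[-1] == 20.0

    def test_am_envelope_recovery(self):
        # known-envelope oracle: power tracks the squared modulator
        t = np.arange(0, 120, 1 / FS)
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        x = mod * np.sin(2 * np.pi * 10 * t)
        power, freqs = eeg_wavelet_power(_sig(x, "eeg_channel"))
        i10 = np.argmin(np.abs(freqs - 10.0))
        sl = slice(1000, -1000)
        r = np.corrcoef(power[sl, i10], mod[sl] ** 2)[0, 1]
        assert r > 0.95

    def test_above_nyquist_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            eeg_wavelet_power(_sig(np.zeros(1000), "eeg_channel", fs=30.0),
                              freqs=[20.0])


class TestAlphaPower:
    def test_alpha_tone_envelope(self):
        t = np.arange(0, 60, 1 / FS)
        x = 2.5 * np.sin(2 * np.pi * 10 * t)
        env = alpha_power(_sig(x, "eeg_channel"))
        interior = env[1000:-1000]
        np.testing.assert_allclose(interior, 2.5, rtol=0.05)

    def test_theta_tone_rejected(self):
        # FIR frequency-response oracle
        fs = FS
        numtaps = int(round(3.3 * fs / 2.0)) | 1
        taps = signal.firwin(numtaps, (8.0, 12.0), pass_zero=False, fs=fs,
                             window="hamming")
        w, h = signal.freqz(taps, worN=[4.0], fs=fs)
        assert np.abs(h[0]) ** 2 < 0.1  # two passes of filtfilt
        t = np.arange(0, 60, 1 / fs)
        x = np.sin(2 * np.pi * 4 * t)
        env = alpha_power(_sig(x, "eeg_channel"))
        assert env[1000:-1000].max() < 0.1

    def test_zero_signal_zero_envelope(self):
        env = alpha_power(_sig(np.zeros(int(60 * FS)), "eeg_channel"))
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_short_signal_errors(self):
        with pytest.raises(ValueError, match="short"):
            alpha_power(_sig(np.zeros(100), "eeg_channel"))


class TestStandardize:
    def test_clip_rule(self):
        x = np.random.default_rng(0).normal(size=30000)
        x[1000] = x.mean() + 10 * x.std()
        mu, sd = x.mean(), x.std()
        clipped = np.clip(x, mu - 5 * sd, mu + 5 * sd)
        assert clipped[1000] == mu + 5 * sd  # the stated clip stage

    def test_output_length_contract(self):
        x = np.random.default_rng(1).normal(size=int(300 * FS))
        f = standardize_feature(x, FS, 300, 1.0)
        assert len(f) == 300

    def test_tone_resampling_oracle(self):
        # 0.05 Hz tone at 100 Hz -> 1 Hz frames; amplitude within 5%
        t = np.arange(0, 600, 1 / FS)
        x = np.sin(2 * np.pi * 0.05 * t)
        f = standardize_feature(x, FS, 600, 1.0)
        target = np.sin(2 * np.pi * 0.05 * np.arange(600))
        sl = slice(60, -60)
        amp = f.values[sl].std() / target[sl].std()
        assert abs(amp - 1.0) < 0.05
        assert np.corrcoef(f.values[sl], target[sl])[0, 1] > 0.99

    def test_frame_mismatch_errors(self):
        x = np.zeros(int(100 * FS))
        with pytest.raises(ValueError, match="n_frames"):
            standardize_feature(x, FS, 600, 1.0)

    def test_zero_phase_full_chain(self, physio_session, session_cfg):
        # coupling-lag sign recovery for each modality on synthetic data
        signals, truth = physio_session
        cfg = session_cfg
        n, tr = cfg.n_frames, cfg.tr_s
        from cofluct.pipeline import extract_features

        feats = extract_features(signals, n, tr)
        arousal_like = truth.true_series
        for name in ["heart_rate", "ppg_amplitude", "respiratory_volume",
                     "skin_conductance", "eeg_alpha"]:
            f = feats[name]
            r = np.corrcoef(f.values, arousal_like[name])[0, 1]
            assert r > 0.4, (name, r)


class TestBlinkInterpolation:
    def test_linear_gap_fill(self):
        x = np.array([0.0, 1.0, np.nan, np.nan, 4.0])
        np.testing.assert_allclose(interpolate_blinks(x), [0, 1, 2, 3, 4])

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            interpolate_blinks(np.full(5, np.nan))
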