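import numpy as np
import pytest
from scipy import signal as sps

from locomep.emg_processing import (
    DEFAULT_MUSCLES,
    EnvelopeRecording,
    GaitCycleMatrix,
    compute_envelope,
    detect_heel_strikes,
    normalize_amplitude,
    segment_and_time_normalize,
)

FS = 2048.0


def make_trial(samples, fs=FS, labels=None):
    samples = np.atleast_2d(samples)
    if labels is None:
        labels = [f"m{i}" for i in range(samples.shape[0])]
    return EnvelopeRecording(muscle_labels=labels, sampling_rate=fs,
                            samples=samples)


def biquad_filtfilt_oracle(sos, x, fs, pad_s=1.0):
    """Independent zero-phase filter: hand-coded DF2T biquad cascade run
    forward then backward over a reflection-padded signal."""

    def cascade(sig):
        y = sig.astype(float).copy()
        for b0, b1, b2, a0, a1, a2 in sos:
            z1 = z2 = 0.0
            out = np.empty_like(y)
            for i, xi in enumerate(y):
                yi = b0 * xi + z1
                z1 = b1 * xi - a1 * yi + z2
                z2 = b2 * xi - a2 * yi
                out[i] = yi
            y = out
        return y

    n = len(x)
    pad = min(int(round(pad_s * fs)), n - 1)
    padded = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    y = cascade(padded)
    y = cascade(y[::-1])[::-1]
    return y[pad:pad + n]


class TestComputeEnvelope:
    def test_dc_input_vanishes(self):
        trial = make_trial(np.full((1, int(2 * FS)), 0.7))
        env = compute_envelope(trial)
        assert np.all(env.samples < 1e-6)

    def test_sinusoid_matches_independent_biquad_oracle(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 100 * t)
        env = compute_envelope(make_trial(x)).samples[0]

        sos_bp = sps.butter(4, [30, 300], btype="bandpass", fs=FS,
                            output="sos")
        sos_lp = sps.butter(4, 3, btype="lowpass", fs=FS, output="sos")
        ref = biquad_filtfilt_oracle(sos_bp, x, FS)
        ref = np.clip(
            biquad_filtfilt_oracle(sos_lp, np.abs(ref), FS), 0, None
        )
        interior = slice(int(1.5 * FS), -int(1.5 * FS))
        assert np.allclose(env[interior], ref[interior], atol=1e-6)
        # envelope of |sin| ~ its mean (2/pi), unit low-pass DC gain
        assert env[interior].mean() == pytest.approx(2 / np.pi, rel=0.02)

    def test_burst_detected_over_drift(self, rng):
        t = np.arange(int(4 * FS)) / FS
        drift = 0.5 * np.sin(2 * np.pi * 5 * t)
        burst = np.where((t > 1.5) & (t < 2.5),
                         np.sin(2 * np.pi * 100 * t), 0.0)
        env = compute_envelope(make_trial(drift + burst)).samples[0]
        burst_mean = env[(t > 1.7) & (t < 2.3)].mean()
        baseline_mean = env[(t > 0.3) & (t < 1.2)].mean()
        assert burst_mean > 5 * baseline_mean

    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError, match="sampling rate"):
            compute_envelope(make_trial(np.zeros((1, 5000)), fs=500))

    def test_rejects_short_signal(self):
        with pytest.raises(ValueError, match="too short"):
            compute_envelope(make_trial(np.zeros((1, 30))))

    def test_rejects_nonfinite(self):
        x = np.zeros((1, 5000))
        x[0, 10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_envelope(make_trial(x))

    def test_zero_phase_burst_not_shifted(self):
        # peak of an isolated in-band burst stays put (< 1 sample)
        t = np.arange(int(2 * FS)) / FS
        gauss = np.exp(-((t - 1.0) ** 2) / (2 * 0.05 ** 2))
        x = gauss * np.sin(2 * np.pi * 100 * t)
        env = compute_envelope(make_trial(x)).samples[0]
        assert abs(int(np.argmax(env)) - int(np.argmax(gauss))) <= 1


class TestNormalizeAmplitude:
    def test_constant_envelope(self):
        trial = make_trial(np.full((1, 1000), 0.4))
        out, peaks = normalize_amplitude([trial])
        assert np.allclose(out[0].samples, 1.0)
        assert peaks[0] == pytest.approx(0.4)

    def test_peak_taken_across_trials(self):
        t1 = make_trial(np.full((1, 1000), 0.3))
        t2 = make_trial(np.full((1, 1000), 0.6))
        out, peaks = normalize_amplitude([t1, t2])
        assert peaks[0] == pytest.approx(0.6)
        assert np.allclose(out[0].samples, 0.5)
        assert np.allclose(out[1].samples, 1.0)

    def test_narrow_pulse_smoothed_peak_matches_bruteforce(self):
        fs = 2000.0
        window = int(round(0.05 * fs))  # 100 samples
        x = np.zeros(2000)
        x[980:1000] = np.linspace(0, 1, 20)  # triangular rise, 20 < window
        x[1000:1020] = np.linspace(1, 0, 20)
        # brute-force centered moving average with edge truncation
        brute = np.array([
            x[max(0, i - window // 2):i + (window + 1) // 2].mean()
            for i in range(len(x))
        ])
        _, peaks = normalize_amplitude([make_trial(x, fs=fs)])
        assert peaks[0] < x.max()
        assert peaks[0] == pytest.approx(brute.max(), abs=1e-9)

    def test_all_zero_channel_flagged(self):
        x = np.vstack([np.zeros(1000), np.full(1000, 0.2)])
        out, peaks = normalize_amplitude([make_trial(x)])
        assert np.isnan(peaks[0]) and peaks[1] == pytest.approx(0.2)
        assert np.allclose(out[0].samples[0], 0.0)

    def test_mismatched_muscle_order_rejected(self):
        a = make_trial(np.zeros((2, 100)), labels=["a", "b"])
        b = make_trial(np.zeros((2, 100)), labels=["b", "a"])
        with pytest.raises(ValueError, match="muscle order"):
            normalize_amplitude([a, b])


class TestDetectHeelStrikes:
    fs = 200.0

    def gait_marker(self, period=1.2, n_cycles=10, noise=0.0, rng=None):
        n = int(n_cycles * period * self.fs)
        t = np.arange(n) / self.fs
        phase = (t - period / 2) / period  # peaks away from the edges
        x = (0.15 * np.cos(2 * np.pi * phase)
             + 0.05 * np.cos(4 * np.pi * phase)
             + 0.02 * np.cos(6 * np.pi * phase))
        if noise:
            x = x + noise * 0.15 * rng.standard_normal(n)
        true_events = period / 2 + period * np.arange(n_cycles)
        return np.column_stack([x, np.zeros(n), np.zeros(n)]), true_events

    def test_periodic_trajectory_events(self):
        marker, truth = self.gait_marker()
        events = detect_heel_strikes(marker, self.fs)
        assert len(events) == len(truth)
        assert np.all(np.abs(np.diff(events) - 1.2) <= 1.5 / self.fs)
        assert np.allclose(events, truth, atol=2 / self.fs)

    def test_constant_trajectory_rejected(self):
        marker = np.tile([1.0, 2.0, 3.0], (1000, 1))
        with pytest.raises(ValueError, match="constant"):
            detect_heel_strikes(marker, self.fs)

    def test_noisy_trajectory_recovers_events(self, rng):
        marker, truth = self.gait_marker(noise=0.1, rng=rng)
        events = detect_heel_strikes(marker, self.fs)
        assert len(events) == len(truth)
        assert np.all(np.abs(events - truth) <= 0.02 * 1.2)

    def test_axis_by_name(self):
        marker, truth = self.gait_marker()
        swapped = marker[:, [1, 0, 2]]
        events = detect_heel_strikes(swapped, self.fs, anterior_axis="y")
        assert len(events) == len(truth)

    def test_unknown_axis_rejected(self):
        marker, _ = self.gait_marker()
        with pytest.raises(ValueError, match="axis"):
            detect_heel_strikes(marker, self.fs, anterior_axis="w")


class TestSegmentAndTimeNormalize:
    def test_linear_ramp(self):
        fs = 2048.0
        n = int(2 * fs)
        ramp = np.linspace(0, 1, n)
        trial = make_trial(ramp, fs=fs)
        cycles = segment_and_time_normalize(trial, [0.0, (n - 1) / fs])
        assert len(cycles) == 1
        v = cycles[0].values[0]
        assert v.shape == (200,)
        assert v[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(v) > 0)

    def test_gaussian_bump_matches_analytic(self):
        fs = 2048.0
        t = np.arange(int(1.5 * fs)) / fs
        mu, sd = 0.6, 0.1
        trial = make_trial(np.exp(-((t - mu) ** 2) / (2 * sd ** 2)), fs=fs)
        start, stop = 0.1, 1.3
        cycles = segment_and_time_normalize(trial, [start, stop])
        grid = start + (stop - start) * np.arange(200) / 200
        expected = np.exp(-((grid - mu) ** 2) / (2 * sd ** 2))
        assert np.allclose(cycles[0].values[0], expected, atol=1e-3)

    def test_three_events_two_cycles(self):
        trial = make_trial(np.zeros(int(3 * FS)))
        cycles = segment_and_time_normalize(trial, [0.1, 1.1, 2.1])
        assert len(cycles) == 2
        assert [c.cycle_index for c in cycles] == [0, 1]

    def test_duration_gate_drops_cycles(self):
        trial = make_trial(np.zeros(int(5 * FS)))
        cycles = segment_and_time_normalize(
            trial, [0.1, 0.3, 1.3, 4.9]  # 0.2 s too short, 3.6 s too long
        )
        assert len(cycles) == 1

    def test_rejects_events_outside_span(self):
        trial = make_trial(np.zeros(int(1 * FS)))
        with pytest.raises(ValueError, match="outside"):
            segment_and_time_normalize(trial, [0.1, 1.5])

    def test_resample_round_trip_smooth_cycle(self):
        # band-limited (<= 3 Hz) cycle survives resampling both ways
        fs = 2048.0
        t = np.arange(int(1.2 * fs)) / fs
        x = 0.5 + 0.3 * np.sin(2 * np.pi * 1.5 * t) + 0.1 * np.cos(2 * np.pi * 2.5 * t)
        trial = make_trial(x, fs=fs)
        cyc = segment_and_time_normalize(trial, [0.0, t[-1]], clip=False)[0]
        from scipy.interpolate import CubicSpline

        grid = t[-1] * np.arange(200) / 200
        back = CubicSpline(grid, cyc.values[0])(t[t < grid[-1]])
        orig = x[t < grid[-1]]
        assert np.sqrt(np.mean((back - orig) ** 2)) < 0.01 * np.sqrt(np.mean(orig ** 2))


def test_full_chain_shape_and_bounds(rng):
    # 15-channel noise trial through the whole chain
    fs = 2048.0
    n = int(6 * fs)
    raw = rng.standard_normal((15, n)) * np.abs(np.sin(
        2 * np.pi * np.arange(n) / fs / 1.2
    ))
    trial = EnvelopeRecording(muscle_labels=list(DEFAULT_MUSCLES),
                             sampling_rate=fs, samples=raw)
    env = compute_envelope(trial)
    assert np.all(env.samples >= 0)
    normalized, peaks = normalize_amplitude([env])
    assert np.all(peaks[np.isfinite(peaks)] > 0)
    cycles = segment_and_time_normalize(normalized[0], [0.5, 1.7, 2.9, 4.1])
    assert len(cycles) == 3
    for c in cycles:
        assert c.values.shape == (15, 200)
        assert np.all((c.values >= 0) & (c.values <= 1))


def test_gait_cycle_matrix_validates_columns():
    with pytest.raises(ValueError, match="200"):
        GaitCycleMatrix(values=np.zeros((3, 100)))
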