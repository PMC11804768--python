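import numpy as np
import pytest

from posturekit.errors import AlignmentError, DataError, ParameterError, SegmentError
from posturekit.signal_pipeline import (
    align_recordings,
    detect_stable_onset,
    downsample,
    estimate_lag,
    filter_recording,
    lowpass_zero_phase,
    sampling_jitter,
    select_segment,
)
from posturekit.synthetic_data import SwaySimConfig, render_devices, simulate_sway, _ou_exact


class TestLowpass:
    def test_dc_gain_unity(self):
        out = lowpass_zero_phase(np.full(500, 5.0), 40.0, 10.0, 4)
        np.testing.assert_allclose(out, 5.0, atol=1e-9)

    def test_attenuation_at_cutoff_is_squared_single_pass(self):
        # forward-backward 4th-order Butterworth: |H|^2 = 1/2 at the cutoff
        rate, cutoff = 100.0, 10.0
        t = np.arange(4000) / rate
        x = np.sin(2 * np.pi * cutoff * t)
        y = lowpass_zero_phase(x, rate, cutoff, 4)
        amp = np.sqrt(2 * np.mean(y[1000:3000] ** 2))  # amplitude via RMS
        assert amp == pytest.approx(0.5, abs=0.02)

    def test_zero_phase_on_sinusoid(self):
        rate = 40.0
        t = np.arange(2000) / rate
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_zero_phase(x, rate, 10.0, 4)
        lags = np.arange(-20, 21)
        corr = [np.dot(x[20:-20], y[20 + l: y.size - 20 + l]) for l in lags]
        assert lags[int(np.argmax(corr))] == 0

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass_zero_phase(np.zeros(100), 40.0, 20.0, 4)

    def test_odd_order_rejected(self):
        with pytest.raises(ParameterError):
            lowpass_zero_phase(np.zeros(100), 40.0, 10.0, 3)


class TestDownsample:
    def test_40_to_20_keeps_every_other(self):
        np.testing.assert_array_equal(
            downsample(np.array([1, 2, 3, 4, 5]), 40, 20), [1, 3, 5])

    def test_100_to_20_keeps_every_fifth(self):
        x = np.arange(20)
        np.testing.assert_array_equal(downsample(x, 100, 20), x[::5])

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ParameterError):
            downsample(np.arange(10), 50, 20)

    def test_variance_preserved_for_bandlimited_noise(self, rng):
        x = rng.standard_normal(40 * 120)
        xf = lowpass_zero_phase(x, 40.0, 8.0, 4)
        xd = downsample(xf, 40, 20)
        assert np.var(xd) == pytest.approx(np.var(xf), rel=0.05)

    def test_filter_downsample_commutes_within_tolerance(self, rng):
        # on band-limited sway (no content above the output Nyquist),
        # filtering at 5 Hz then decimating 40->20 Hz matches decimating
        # then filtering, within 2% RMS
        sway = lowpass_zero_phase(_ou_exact(40 * 60, 1 / 40, 0.4, 1.0, rng),
                                  40.0, 8.0, 4)
        a = downsample(lowpass_zero_phase(sway, 40.0, 5.0, 4), 40, 20)
        b = lowpass_zero_phase(downsample(sway, 40, 20), 20.0, 5.0, 4)
        rms_diff = np.sqrt(np.mean((a - b) ** 2))
        assert rms_diff < 0.02 * np.sqrt(np.mean(a ** 2))


class TestEstimateLag:
    def test_constructed_shift_recovered(self, rng):
        x = _ou_exact(1000, 0.05, 1.0, 1.0, rng)
        a, b = x[:600], x[13:613]  # b starts 13 samples later than a
        assert estimate_lag(a, b, 50) == 13

    def test_identical_series_lag_zero(self, rng):
        x = _ou_exact(600, 0.05, 1.0, 1.0, rng)
        assert estimate_lag(x, x, 50) == 0

    def test_anticorrelated_warns_and_reports_peak(self, rng):
        x = _ou_exact(600, 0.05, 1.0, 1.0, rng)
        with pytest.warns(UserWarning, match="anticorrelated"):
            lag = estimate_lag(x, -x[5:605], 50)
        assert lag == 5

    def test_zero_variance_rejected(self):
        with pytest.raises(AlignmentError):
            estimate_lag(np.ones(600), np.ones(600), 10)


class TestAlign:
    @pytest.mark.parametrize("lag_s", [0.65, 1.95])
    def test_injected_lag_removed(self, run_cfg, lag_s):
        sim = SwaySimConfig(seed=11, duration_s=30.0, device_lag_s=lag_s,
                            board_noise_sd_n=0.0, plate_noise_sd_n=0.0,
                            board_ml_noise_sd_n=0.0, jitter_sd_ms=0.0)
        truth = simulate_sway(sim)
        board, plate = render_devices(truth, sim, run_cfg)
        ba, pa = align_recordings(filter_recording(board, run_cfg),
                                  filter_recording(plate, run_cfg), run_cfg)
        # the board head trimmed by exactly the injected lag (grid-aligned)
        lag_board_samples = int(round(lag_s * 40))
        head_trim = len(board) - round(min(ba.duration_s, 30.0) * 40)
        assert head_trim == pytest.approx(lag_board_samples, abs=0)
        # after alignment both bottom-left signals agree at lag 0
        from posturekit.signal_pipeline import _matching_signal
        sb = downsample(_matching_signal(ba, run_cfg), 40, 20)
        sp = downsample(_matching_signal(pa, run_cfg), 100, 20)
        assert estimate_lag(sb, sp, 40) == 0

    def test_aligned_pair_only_duration_trimmed(self, run_cfg, noise_free_trial):
        _, _, board, plate = noise_free_trial  # lag-free trial
        ba, pa = align_recordings(filter_recording(board, run_cfg),
                                  filter_recording(plate, run_cfg), run_cfg)
        assert abs(ba.duration_s - pa.duration_s) <= 1.0 / 40
        np.testing.assert_array_equal(ba.channels["bl"],
                                      filter_recording(board, run_cfg).channels["bl"][:len(ba)])

    def test_constant_signals_rejected(self, run_cfg):
        from conftest import make_corner_recording
        idx = make_corner_recording({c: np.full(1200, 200.0) for c in ("tl", "tr", "bl", "br")})
        from posturekit.io_formats import RawRecording
        n = 3000
        ref = RawRecording("wrench_plate", 100.0, np.arange(n) / 100.0, {
            "fx": np.zeros(n), "fy": np.zeros(n), "fz": np.full(n, 800.0),
            "mx": np.zeros(n), "my": np.zeros(n), "mz": np.zeros(n)})
        with pytest.raises(AlignmentError):
            align_recordings(idx, ref, run_cfg)


class TestOnset:
    def test_constant_load_onset_zero(self):
        assert detect_stable_onset(np.full(400, 780.0), 40.0) == 0

    def test_step_onto_plate(self):
        rate = 40.0
        t = np.arange(int(30 * rate)) / rate
        force = np.where(t < 1.5, 780.0 * t / 1.5, 780.0)
        onset = detect_stable_onset(force, rate)
        assert 1.3 * rate <= onset <= 2.0 * rate

    def test_never_stable_falls_back_with_warning(self):
        rate = 40.0
        n = int(20 * rate)
        force = 700.0 + 70.0 * (-1.0) ** np.arange(n)  # +-10% every sample
        with pytest.warns(UserWarning, match="stable"):
            assert detect_stable_onset(force, rate) == 0

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            detect_stable_onset(np.ones(50), 40.0)


class TestSelectSegment:
    def test_central_bipedal_window(self, run_cfg):
        seg = select_segment(600, 20.0, "bipedal", 0, run_cfg)
        assert (seg.start_index, seg.length) == (100, 400)
        assert seg.duration_s == pytest.approx(20.0)

    def test_exactly_fitting_segment(self, run_cfg):
        seg = select_segment(400 + 7, 20.0, "bipedal", 7, run_cfg)
        assert seg.start_index == 7 and seg.length == 400

    def test_unipedal_duration(self, run_cfg):
        seg = select_segment(2000, 100.0, "unipedal", 0, run_cfg)
        assert seg.duration_s == pytest.approx(15.0)

    def test_insufficient_duration_reports_both_sides(self, run_cfg):
        with pytest.raises(SegmentError, match="20"):
            select_segment(200, 20.0, "bipedal", 0, run_cfg)


class TestJitter:
    def test_uniform_intervals_zero_sd(self):
        stats = sampling_jitter([np.arange(100) * 0.025])
        assert stats.per_recording_sd_ms[0] == pytest.approx(0.0, abs=1e-9)

    def test_alternating_intervals_closed_form(self):
        dt = np.tile([0.024, 0.026], 50)
        t = np.concatenate(([0.0], np.cumsum(dt)))
        stats = sampling_jitter([t])
        assert stats.per_recording_sd_ms[0] == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_jitter_group_mean(self, rng):
        sets = []
        for _ in range(40):
            dt = 0.025 + rng.normal(0, 0.001, 799)
            sets.append(np.concatenate(([0.0], np.cumsum(dt))))
        stats = sampling_jitter(sets)
        assert 0.8 <= stats.mean_ms <= 1.2
        assert stats.ci95_low_ms <= stats.mean_ms <= stats.ci95_high_ms

    def test_too_few_timestamps_rejected(self):
        with pytest.raises(DataError):
            sampling_jitter([np.array([0.0, 0.025])])
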