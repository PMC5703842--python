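"""Tests of referencing, band power, artifacts, traces, and wavelet maps."""

import numpy as np
import pytest
from scipy import stats

from bartstop import lfp_processing as lp
from bartstop import synthetic_data as sd
from bartstop.containers import BandPowerSeries, LfpRecording

FS = 1000.0


def sine_recording(freq_hz=6.0, amp=1.0, dur_s=20.0, n_channels=1, fs=FS):
    t = np.arange(0, dur_s, 1 / fs)
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (n_channels, 1))
    return LfpRecording(data=data, fs_hz=fs, channel_ids=[f"ch{i}" for i in range(n_channels)])


class TestCommonAverageReference:
    def test_cross_channel_mean_zero_to_machine_precision(self, small_session):
        car = lp.common_average_reference(small_session["lfp"])
        assert np.abs(car.data.mean(axis=0)).max() < 1e-12

    def test_shared_artifact_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((3, 5000))
        artifact = 50.0 * np.sin(np.linspace(0, 40, 5000))
        rec_clean = LfpRecording(base - base.mean(axis=0), FS, ["a", "b", "c"])
        rec_dirty = LfpRecording(
            rec_clean.data + artifact, FS, ["a", "b", "c"]
        )
        car = lp.common_average_reference(rec_dirty)
        assert np.allclose(car.data, rec_clean.data, atol=1e-10)

    def test_antisymmetric_pair_unchanged(self):
        rec = sine_recording(n_channels=2)
        rec = rec.copy_with(data=np.vstack([rec.data[0], -rec.data[0]]))
        car = lp.common_average_reference(rec)
        assert np.allclose(car.data, rec.data)

    def test_single_channel_degenerate_warns(self):
        rec = sine_recording(n_channels=1)
        with pytest.warns(UserWarning, match="single channel"):
            car = lp.common_average_reference(rec)
        assert np.all(car.data == 0)


class TestBandPower:
    def test_in_band_sinusoid_power_is_amplitude_squared(self):
        bp = lp.band_power(sine_recording(6.0, amp=1.0), lp.CANONICAL_BANDS["theta"])[0]
        mid = bp.power[400:-400]
        assert np.abs(mid - 1.0).max() < 0.02

    def test_out_of_band_rejection(self):
        bp = lp.band_power(sine_recording(6.0), lp.CANONICAL_BANDS["beta"])[0]
        assert bp.power[400:-400].mean() < 1e-4

    def test_quadratic_amplitude_scaling(self):
        p1 = lp.band_power(sine_recording(6.0, amp=1.0), lp.CANONICAL_BANDS["theta"])[0]
        p2 = lp.band_power(sine_recording(6.0, amp=2.0), lp.CANONICAL_BANDS["theta"])[0]
        ratio = p2.power[400:-400] / p1.power[400:-400]
        assert np.median(ratio) == pytest.approx(4.0, rel=1e-3)

    def test_band_above_nyquist_rejected(self):
        rec = sine_recording(fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lp.band_power(rec, lp.CANONICAL_BANDS["gamma"], target_fs_hz=100.0)

    def test_output_rate_and_mask_downsampling(self):
        rec = sine_recording(6.0)
        mask = np.zeros(rec.data.shape, bool)
        mask[0, 5000:5500] = True
        rec = rec.copy_with(artifact_mask=mask)
        bp = lp.band_power(rec, lp.CANONICAL_BANDS["theta"])[0]
        assert bp.fs_hz == 200.0
        assert len(bp.power) == rec.n_samples // 5
        assert bp.mask[1000:1100].all()  # 5 s..5.5 s at 200 Hz
        assert not bp.mask[:990].any()


class TestDetectArtifacts:
    def test_clean_sinusoid_unmasked(self):
        mask = lp.detect_artifacts(sine_recording(6.0))
        assert mask.mean() == 0.0

    def test_saturation_plateau_masked_with_guard(self):
        rec = sine_recording(6.0, dur_s=10.0)
        data = rec.data.copy()
        data[0, 3000:4000] = 5.0
        mask = lp.detect_artifacts(rec.copy_with(data=data))
        assert mask[0, 3000:4000].all()
        assert mask[0, 2950] and mask[0, 4049]  # 100 ms guard

    def test_amplitude_burst_masked_by_power_rule(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        x[6000:6200] *= 20.0
        mask = lp.detect_artifacts(LfpRecording(x[None, :], FS, ["a"]))
        assert mask[0, 6050:6150].mean() > 0.9


class TestPeriEventTrace:
    def test_stationary_power_gives_flat_near_zero_trace(self):
        rng = np.random.default_rng(2)
        power = np.exp(rng.normal(0, 0.3, 120_000))
        bp = BandPowerSeries("a", "theta", power, 200.0)
        trace = lp.peri_event_trace(bp, np.arange(5, 595, 4.0), (-2.0, 1.0))
        # median over ~150 events of unit-variance z-scores: tight around 0
        assert abs(np.nanmean(trace.trace)) < 0.05
        assert np.nanmax(np.abs(trace.trace)) < 0.5

    def test_single_event_trace_equals_its_log_power(self):
        rng = np.random.default_rng(3)
        power = np.exp(rng.normal(0, 1, 4000))
        bp = BandPowerSeries("a", "theta", power, 200.0)
        trace = lp.peri_event_trace(bp, [10.0], (-1.0, 1.0), z_score=False)
        i0 = int(10.0 * 200) + int(-1.0 * 200)
        expected = np.log(power[i0 : i0 + 400])
        assert np.allclose(trace.trace, expected)

    def test_masked_samples_excluded_and_counts_reported(self):
        power = np.ones(4000)
        mask = np.zeros(4000, bool)
        mask[2000:2200] = True
        bp = BandPowerSeries("a", "theta", power, 200.0, mask=mask)
        trace = lp.peri_event_trace(bp, [10.0, 15.0], (-1.0, 1.0), min_events=1)
        # event at 10 s has its first second masked; counts drop to 1 there
        assert trace.n_events.min() == 1
        assert trace.n_events.max() == 2

    def test_simulated_theta_ramp_recovered(self):
        cfg = sd.TaskConfig(n_trials=70, frac_forced=0.0, include_gray=False, seed=50)
        trials = sd.simulate_agent_stops(
            sd.generate_trials(cfg), sd.AgentPolicy(), cfg, seed=51
        )
        params = sd.NeuralGenParams(
            lfp_bands=[sd.LfpBandTruth("theta", 6.0, 1.0, ramp_gain=2.0, ramp_onset_s=2.0)],
            n_channels=2,
        )
        lfp = sd.simulate_lfp(trials, params, seed=52)
        bp = lp.band_power(lfp, lp.CANONICAL_BANDS["theta"])
        banked = (trials["type"] == "free") & (trials["outcome"] == "banked")
        stops = (
            trials.loc[banked, "t_start_s"] + trials.loc[banked, "t_stop_s"]
        ).to_numpy()
        assert len(stops) >= 50
        traces = [lp.peri_event_trace(s, stops, (-2.0, 0.0)) for s in bp]
        avg = lp.average_traces(traces)
        ok = ~np.isnan(avg.trace)
        slope, _, _, p, _ = stats.linregress(avg.times_s[ok], avg.trace[ok])
        assert slope > 0 and p < 0.05

    def test_no_ramp_control_slope_not_significant(self):
        # ramp gain 1 (no signal): pre-stop slope should be null
        cfg = sd.TaskConfig(n_trials=50, frac_forced=0.0, include_gray=False, seed=53)
        trials = sd.simulate_agent_stops(
            sd.generate_trials(cfg), sd.AgentPolicy(), cfg, seed=54
        )
        params = sd.NeuralGenParams(
            lfp_bands=[sd.LfpBandTruth("theta", 6.0, 1.0, ramp_gain=1.0)], n_channels=2
        )
        lfp = sd.simulate_lfp(trials, params, seed=55)
        bp = lp.band_power(lfp, lp.CANONICAL_BANDS["theta"])[0]
        banked = (trials["type"] == "free") & (trials["outcome"] == "banked")
        stops = (
            trials.loc[banked, "t_start_s"] + trials.loc[banked, "t_stop_s"]
        ).to_numpy()
        # per-trial slopes of log power: mean not significantly positive
        trace = lp.peri_event_trace(bp, stops, (-2.0, 0.0))
        ok = ~np.isnan(trace.trace)
        slope, _, _, p, _ = stats.linregress(trace.times_s[ok], trace.trace[ok])
        assert not (slope > 0 and p < 1e-4)


class TestWaveletTfr:
    def test_pure_tone_ridge_at_nearest_grid_frequency(self):
        t = np.arange(0, 20, 1 / 200.0)
        x = np.sin(2 * np.pi * 10.0 * t)
        tfr = lp.wavelet_tfr(x, 200.0)
        interior = slice(800, 3200)
        ridge = tfr.freqs_hz[np.argmax(tfr.values[:, interior], axis=0)]
        nearest = tfr.freqs_hz[np.argmin(np.abs(tfr.freqs_hz - 10.0))]
        assert np.all(ridge == nearest)

    def test_two_tones_two_ridges(self):
        t = np.arange(0, 20, 1 / 200.0)
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 40 * t)
        tfr = lp.wavelet_tfr(x, 200.0)
        mean_spec = tfr.values[:, 800:3200].mean(axis=1)
        # distinct local maxima near each tone, a deep valley between
        low = mean_spec[tfr.freqs_hz < 15]
        high = mean_spec[tfr.freqs_hz >= 15]
        f_low = tfr.freqs_hz[tfr.freqs_hz < 15][np.argmax(low)]
        f_high = tfr.freqs_hz[tfr.freqs_hz >= 15][np.argmax(high)]
        assert abs(f_low - 5) < 1.0
        assert abs(f_high - 40) < 4.0
        mid = mean_spec[(tfr.freqs_hz > 10) & (tfr.freqs_hz < 25)]
        assert mid.max() < 0.01 * min(low.max(), high.max())

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lp.wavelet_tfr(np.zeros(1000), 80.0)


class TestDbMaps:
    @pytest.fixture()
    def flat_map(self):
        freqs = lp.default_freq_grid(10)
        times = np.linspace(-2.0, 1.0, 200)
        vals = np.ones((10, 200))
        from bartstop.containers import TimeFrequencyMap

        return TimeFrequencyMap(freqs, times, vals)

    def test_baseline_equality_maps_to_zero_db_exactly(self, flat_map):
        out = lp.normalize_db(flat_map, baseline_s=(-1.5, -0.5))
        assert np.all(out.values == 0.0)

    def test_tenfold_power_is_ten_db(self, flat_map):
        tfr = flat_map.copy_with(values=flat_map.values * 10.0)
        out = lp.normalize_db(tfr, trials=[flat_map], baseline_s=(-1.5, -0.5))
        assert np.allclose(out.values, 10.0)

    def test_half_power_is_minus_three_db(self, flat_map):
        tfr = flat_map.copy_with(values=flat_map.values / 2.0)
        out = lp.normalize_db(tfr, trials=[flat_map], baseline_s=(-1.5, -0.5))
        assert np.allclose(out.values, -10 * np.log10(2.0))

    def test_contrast_antisymmetry_and_scaling(self, flat_map):
        rng = np.random.default_rng(4)
        a = flat_map.copy_with(values=np.exp(rng.normal(0, 1, flat_map.values.shape)))
        b = flat_map.copy_with(values=np.exp(rng.normal(0, 1, flat_map.values.shape)))
        ab = lp.contrast_db(a, b)
        ba = lp.contrast_db(b, a)
        assert np.allclose(ab.values, -ba.values)
        doubled = lp.contrast_db(a.copy_with(values=2 * a.values), a)
        assert np.allclose(doubled.values, 10 * np.log10(2.0))

    def test_identical_conditions_give_zero_contrast(self, flat_map):
        out = lp.contrast_db(flat_map, flat_map)
        assert np.all(out.values == 0.0)
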