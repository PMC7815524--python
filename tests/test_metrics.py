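"""Per-sweep measurements: stimulus detection, fiber volley, initial slope,
rectified AUC, and the modified Coastline Burst Index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fieldlab as fl
from fieldlab.errors import DetectionError, ValidationError
from fieldlab.metrics import baseline_voltage


class TestStimulusDetection:
    def test_annotation_passthrough(self, make_sweep_fn):
        sw = make_sweep_fn(np.zeros(1000), stimulus_times=[20.0])
        assert fl.detect_stimulus_onset(sw) == 20.0

    def test_detects_constructed_artifact(self, make_sweep_fn):
        v = np.zeros(1000)
        v[350:353] = 5.0  # artifact moved to 35 ms, no annotation
        sw = make_sweep_fn(v)
        assert fl.detect_stimulus_onset(sw) == pytest.approx(35.0, abs=0.1)

    def test_detection_accuracy_under_noise(self):
        errs = []
        for seed in range(100):
            p = fl.preset("air", seed=seed, artifact_amp=5.0)
            sw = fl.simulate_sweep(p, 100.0, [20.0])
            sw.stimulus_times = []  # strip annotation
            errs.append(abs(fl.detect_stimulus_onset(sw) - 20.0))
        assert max(errs) <= 0.2

    def test_no_artifact_raises(self, make_sweep_fn):
        rng = np.random.default_rng(0)
        sw = make_sweep_fn(rng.normal(0, 0.05, 1000))
        with pytest.raises(DetectionError):
            fl.detect_stimulus_onset(sw)


class TestFiberVolley:
    def test_zero_recruitment_measures_zero(self, air_quiet):
        sw = fl.simulate_sweep(air_quiet, 0.0, [20.0])
        assert fl.measure_fiber_volley(sw, (20.5, 22.5), stim_time=20.0) == 0.0

    def test_recovers_closed_form_amplitude(self, air_quiet):
        sw = fl.simulate_sweep(air_quiet, 200.0, [20.0])
        true = fl.fiber_volley_amplitude(air_quiet, 200.0)
        got = fl.measure_fiber_volley(sw, (20.5, 22.5), stim_time=20.0)
        assert got == pytest.approx(true, rel=0.01)

    def test_hill_curve_recovered_across_ramp(self, air_quiet):
        meas, true = [], []
        for i in np.arange(10.0, 321.0, 10.0):
            sw = fl.simulate_sweep(air_quiet, float(i), [20.0])
            meas.append(fl.measure_fiber_volley(sw, (20.5, 22.5), stim_time=20.0))
            true.append(fl.fiber_volley_amplitude(air_quiet, float(i)))
        meas, true = np.array(meas), np.array(true)
        ss_res = np.sum((meas - true) ** 2)
        ss_tot = np.sum((true - true.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_offset_invariance(self, single_response):
        sw = single_response
        shifted = fl.Sweep(samples=sw.samples + 3.7, stimulus_times=[20.0])
        a = fl.measure_fiber_volley(sw, (20.5, 22.5), stim_time=20.0)
        b = fl.measure_fiber_volley(shifted, (20.5, 22.5), stim_time=20.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_window_outside_sweep(self, single_response):
        with pytest.raises(ValidationError):
            fl.measure_fiber_volley(single_response, (90.0, 150.0), stim_time=20.0)


class TestInitialSlope:
    def _ramp_sweep(self, slope=-0.4):
        # flat, then a linear falling segment, then flat: chord slope is exact
        t = np.arange(0, 100, 0.1)
        v = np.zeros_like(t)
        seg = (t >= 30) & (t < 40)
        v[seg] = slope * (t[seg] - 30)
        v[t >= 40] = slope * 10
        return fl.Sweep(samples=v, stimulus_times=[20.0])

    def test_linear_segment_identity(self):
        sw = self._ramp_sweep(-0.4)
        fit = fl.measure_initial_slope(sw, (25.0, 60.0), stim_time=20.0,
                                       smooth_ms=0.0)
        assert fit.slope == pytest.approx(0.40, rel=0.01)
        assert fit.signed_slope < 0

    def test_scaling_linearity(self):
        a = fl.measure_initial_slope(self._ramp_sweep(-0.2), (25.0, 60.0),
                                     stim_time=20.0, smooth_ms=0.0)
        b = fl.measure_initial_slope(self._ramp_sweep(-0.4), (25.0, 60.0),
                                     stim_time=20.0, smooth_ms=0.0)
        assert b.slope == pytest.approx(2 * a.slope, rel=1e-6)

    def test_dual_exponential_matches_dense_grid_oracle(self):
        # oracle: least-squares line over the 20-80% rising span, computed on
        # a 100x oversampled closed-form waveform
        tau_r, tau_d, peak = 2.0, 20.0, 1.0
        dt_f = 0.001
        t_f = np.arange(0.0, 60.0, dt_f)
        g = np.exp(-t_f / tau_d) - np.exp(-t_f / tau_r)
        gmax = g.max()
        g = g / gmax * peak
        i_pk = int(np.argmax(g))
        rise = g[:i_pk + 1]
        i20 = int(np.searchsorted(rise, 0.2 * peak))
        i80 = int(np.searchsorted(rise, 0.8 * peak))
        oracle = np.polyfit(t_f[i20:i80], g[i20:i80], 1)[0]

        onset = 23.0
        t = np.arange(0, 100, 0.1)
        s = np.clip(t - onset, 0.0, None)
        v = -peak * (np.exp(-s / tau_d) - np.exp(-s / tau_r)) / gmax
        sw = fl.Sweep(samples=v, stimulus_times=[20.0])
        fit = fl.measure_initial_slope(sw, (22.5, 50.0), stim_time=20.0)
        assert fit.slope == pytest.approx(oracle, rel=0.02)
        assert fit.peak_amplitude == pytest.approx(peak, rel=0.02)

    def test_offset_invariance(self, single_response):
        sw = single_response
        shifted = fl.Sweep(samples=sw.samples - 2.2, stimulus_times=[20.0])
        a = fl.measure_initial_slope(sw, (22.5, 50.0), stim_time=20.0)
        b = fl.measure_initial_slope(shifted, (22.5, 50.0), stim_time=20.0)
        assert a.slope == pytest.approx(b.slope, abs=1e-9)

    def test_too_few_samples_raises(self):
        t = np.arange(40.0)
        v = np.where(t >= 12, -0.5 * (t - 12), 0.0)
        sw = fl.Sweep(samples=v, sample_interval=1.0, stimulus_times=[10.0])
        with pytest.raises(ValidationError, match="denser"):
            fl.measure_initial_slope(sw, (12.0, 20.0), stim_time=10.0,
                                     rise_fraction=(0.45, 0.55), smooth_ms=0.0)


class TestAUC:
    def test_square_deflection_area(self, make_sweep_fn):
        v = np.zeros(1500)
        v[300:800] = -2.0  # -2 mV for 50 ms
        sw = make_sweep_fn(v, stimulus_times=[20.0])
        auc = fl.measure_auc(sw, 20.0, 100.0, stim_time=20.0)
        assert auc == pytest.approx(100.0, rel=0.01)

    def test_flat_sweep_zero(self, make_sweep_fn):
        sw = make_sweep_fn(np.zeros(1500), stimulus_times=[20.0])
        assert fl.measure_auc(sw, 20.0, 100.0, stim_time=20.0) == 0.0

    def test_additivity_across_split(self, single_response):
        sw = single_response
        whole = fl.measure_auc(sw, 20.0, 60.0, stim_time=20.0)
        left = fl.measure_auc(sw, 20.0, 30.0, stim_time=20.0)
        right = fl.measure_auc(sw, 50.0, 30.0, stim_time=20.0)
        # up to one-sample boundary error
        assert whole == pytest.approx(left + right, abs=0.05)

    def test_burst_matches_oversampled_oracle(self, air_quiet):
        pulses = [20.0, 30.0, 40.0, 50.0, 60.0]
        sw = fl.simulate_sweep(air_quiet, 100.0, pulses, duration=150.0)
        auc = fl.measure_auc(sw, 20.0, 100.0, stim_time=20.0)
        # closed form evaluated on a 100x finer grid, trapezoid there
        from test_simulate import _closed_form_trace
        t_f = np.arange(20.0, 120.0 + 1e-9, 0.001)
        v_f = _closed_form_trace(air_quiet, 100.0, pulses, t_f)
        oracle = np.trapezoid(np.maximum(0.0, -v_f), dx=0.001)
        assert auc == pytest.approx(oracle, rel=0.005)

    def test_window_exceeding_sweep(self, single_response):
        with pytest.raises(ValidationError):
            fl.measure_auc(single_response, 20.0, 500.0, stim_time=20.0)


class TestMCBI:
    def test_constant_trace_zero(self, make_sweep_fn):
        sw = make_sweep_fn(np.full(2000, 1.3))
        assert fl.compute_mcbi(sw).value == 0.0

    def test_hand_sum(self):
        # in-window samples [0, 1, 0, 1, 0] -> sum of |diffs| = 4
        sw = fl.Sweep(samples=np.array([0.0, 1.0, 0.0, 1.0, 0.0]),
                      sample_interval=25.0)
        res = fl.compute_mcbi(sw, (0.0, 100.0))
        assert res.value == pytest.approx(4.0)
        assert res.n_samples == 5

    def test_matches_loop_oracle_on_simulated_burst(self):
        p = fl.preset("hyperoxia", seed=21)
        rec = fl.simulate_experiment(p, fl.build_tbs())
        for sw in rec:
            got = fl.compute_mcbi(sw, (25.0, 125.0)).value
            i0, i1 = sw.index_at(25.0), sw.index_at(125.0)
            acc = 0.0
            for x in range(i0, i1):
                acc += abs(sw.samples[x + 1] - sw.samples[x])
            assert got == acc  # exact

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(offset=st.floats(-10, 10), scale=st.floats(-5, 5))
    def test_offset_invariance_and_scaling(self, offset, scale):
        rng = np.random.default_rng(9)
        v = rng.normal(size=1300)
        sw = fl.Sweep(samples=v)
        base = fl.compute_mcbi(sw, (25.0, 125.0)).value
        shifted = fl.compute_mcbi(fl.Sweep(samples=v + offset), (25.0, 125.0)).value
        scaled = fl.compute_mcbi(fl.Sweep(samples=v * scale), (25.0, 125.0)).value
        assert shifted == pytest.approx(base, rel=1e-12)
        assert scaled == pytest.approx(abs(scale) * base, rel=1e-12)

    def test_population_spike_increases_mcbi(self, air_quiet):
        sw = fl.simulate_sweep(air_quiet, 100.0, [20.0], duration=150.0)
        base = fl.compute_mcbi(sw, (25.0, 125.0)).value
        v = sw.samples.copy()
        t = sw.time
        x = np.clip((t - 45.0) / 0.5, 0.0, None)
        v -= 0.5 * x * np.exp(1 - x)  # add one spike on the decay
        spiked = fl.compute_mcbi(fl.Sweep(samples=v, stimulus_times=[20.0]),
                                 (25.0, 125.0)).value
        assert spiked > base

    def test_window_too_short(self, make_sweep_fn):
        sw = make_sweep_fn(np.zeros(2000))
        with pytest.raises(ValidationError):
            fl.compute_mcbi(sw, (25.0, 25.05))


class TestNormalize:
    def test_identity_and_hand_division(self):
        np.testing.assert_allclose(fl.normalize_metric([2.0, 4.0], 2.0), [1.0, 2.0])
        np.testing.assert_allclose(fl.normalize_metric([3.0, 3.0], 3.0), [1.0, 1.0])

    def test_self_normalization_mean_is_one(self):
        vals = [0.8, 1.1, 1.4, 0.95]
        out = fl.normalize_metric(vals, float(np.mean(vals)))
        assert float(np.mean(out)) == pytest.approx(1.0, abs=1e-15)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            fl.normalize_metric([1.0], 0.0)


class TestBaseline:
    def test_baseline_is_prestimulus_mean(self, make_sweep_fn):
        v = np.concatenate([np.full(180, 0.5), np.zeros(820)])
        sw = make_sweep_fn(v, stimulus_times=[20.0])
        assert baseline_voltage(sw, 20.0) == pytest.approx(0.5)
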