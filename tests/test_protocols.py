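"""Experiment-level analyses: TBS construction, I/O curves, paired-pulse
ratio, the baseline-stability inclusion rule, LTP magnitude, and tetanus
depolarization."""

import dataclasses

import numpy as np
import pytest

import fieldlab as fl
from fieldlab.errors import AnalysisError, ValidationError


class TestBuildTBS:
    def test_pulse_arithmetic(self):
        proto = fl.build_tbs()
        times = proto.pulse_times
        assert len(times) == 5 * 10
        assert times[:5] == [0.0, 10.0, 20.0, 30.0, 40.0]
        onsets = times[::5]
        assert onsets == [200.0 * b for b in range(10)]
        within = np.diff(np.asarray(times).reshape(10, 5), axis=1)
        assert np.all(within == 10.0)


class TestAnalyzeIO:
    def test_noise_free_fv_matches_hill_closed_form(self, air_quiet):
        rec = fl.simulate_experiment(air_quiet, fl.build_io_ramp())
        io = fl.analyze_io(rec)
        true = fl.fiber_volley_amplitude(air_quiet, 320.0)
        assert io.max_fv == pytest.approx(true, rel=0.01)

    def test_noise_free_slope_monotone_in_intensity(self, air_quiet):
        io = fl.analyze_io(fl.simulate_experiment(air_quiet, fl.build_io_ramp()))
        assert np.all(np.diff(io.mean_slope) >= -1e-12)

    def test_hyperoxia_exceeds_air_at_matched_seed(self):
        ios = {}
        for cond in ("air", "hyperoxia"):
            p = fl.preset(cond, seed=31)
            ios[cond] = fl.analyze_io(fl.simulate_experiment(p, fl.build_io_ramp()))
        assert ios["hyperoxia"].max_slope > ios["air"].max_slope
        assert ios["hyperoxia"].max_fv > ios["air"].max_fv

    def test_means_are_arithmetic_means_of_per_sweep_values(self, air_quiet):
        io = fl.analyze_io(fl.simulate_experiment(air_quiet, fl.build_io_ramp()))
        for k, inten in enumerate(io.intensities):
            assert io.mean_slope[k] == pytest.approx(
                np.mean(io.per_sweep_slope[inten]), abs=1e-15)

    def test_underpopulated_intensity_flagged(self, air_quiet):
        rec = fl.simulate_experiment(air_quiet, fl.build_io_ramp())
        short = fl.Recording(sweeps=rec.sweeps[:-3], protocol=rec.protocol)
        with pytest.warns(UserWarning, match="<6 sweeps"):
            io = fl.analyze_io(short)
        assert io.underpopulated == [320.0]

    def test_half_max_targeting(self, air_quiet):
        io = fl.analyze_io(fl.simulate_experiment(air_quiet, fl.build_io_ramp()))
        # generator half-recruitment current is 100 uA; slope tracks the
        # fiber volley, so the nearest-to-half intensity should sit close by
        assert abs(io.half_max_intensity() - air_quiet.i_half) <= 20.0


class TestAnalyzePPR:
    def test_identical_artificial_responses_give_unity(self):
        # two fabricated identical fEPSPs, far enough apart not to overlap
        t = np.arange(0, 300, 0.1)
        v = np.zeros_like(t)
        for onset in (23.0, 173.0):
            s = np.clip(t - onset, 0.0, None)
            v -= (np.exp(-s / 20.0) - np.exp(-s / 2.0))
        sw = fl.Sweep(samples=v, stimulus_times=[20.0, 170.0])
        rec = fl.Recording(sweeps=[sw], protocol=fl.StimulusProtocol(
            kind="paired_pulse", isi=150.0, pulse_times=[20.0, 170.0], n_sweeps=1))
        res = fl.analyze_ppr(rec)
        assert res.ppr == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("f50", [1.0, 1.5])
    def test_noise_free_calibration(self, f50):
        p = fl.preset("air", noise_sd=0.0, seed=2, f50=f50)
        rec = fl.simulate_experiment(p, fl.build_paired_pulse(n_sweeps=1))
        assert fl.analyze_ppr(rec).ppr == pytest.approx(f50, rel=0.01)

    def test_noisy_recovery_across_seeds(self):
        vals = []
        for seed in range(20):
            p = fl.preset("air", seed=300 + seed)  # f50 = 1.5, noise 0.05 mV
            rec = fl.simulate_experiment(p, fl.build_paired_pulse(n_sweeps=12))
            vals.append(fl.analyze_ppr(rec).ppr)
        assert np.mean(vals) == pytest.approx(1.5, rel=0.05)

    def test_single_stimulus_sweep_rejected(self, air_quiet):
        rec = fl.simulate_experiment(air_quiet, fl.build_baseline(2.0))
        with pytest.raises(AnalysisError):
            fl.analyze_ppr(rec)


class TestBaselineStability:
    def test_constant_slopes_included_with_zero_variance(self):
        t = np.arange(120) / 6.0
        ok, pct = fl.check_baseline_stability(t, np.full(120, 0.2))
        assert ok
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_alternating_20pct_bins_excluded(self):
        # bins alternate +/-20% around the mean -> CV 20% > 8% limit
        t = np.arange(120) / 6.0
        s = np.where((np.floor(t) % 2) == 0, 1.2, 0.8) * 0.2
        ok, pct = fl.check_baseline_stability(t, s)
        assert not ok
        assert pct == pytest.approx(20.0, rel=1e-6)

    def test_small_simulated_drift_included(self):
        for seed in range(20):
            p = fl.preset("air", seed=700 + seed)
            rec = fl.simulate_experiment(p, fl.build_ltp_experiment())
            res = fl.analyze_ltp(rec)
            assert res.included

    def test_exclusion_monotone_in_constructed_cv(self):
        rng = np.random.default_rng(4)
        t = np.arange(120) / 6.0
        shape = rng.normal(size=20)
        shape -= shape.mean()
        shape /= np.sqrt(np.mean(shape ** 2))
        decisions = []
        for cv in (0.02, 0.06, 0.09, 0.15):
            s = 0.2 * (1.0 + cv * shape[np.floor(t).astype(int)])
            ok, _ = fl.check_baseline_stability(t, s)
            decisions.append(ok)
        assert decisions == sorted(decisions, reverse=True)  # once out, stays out

    def test_too_few_sweeps(self):
        with pytest.raises(ValidationError):
            fl.check_baseline_stability([0.0, 1.0], [0.1, 0.1])


class TestAnalyzeLTP:
    def test_null_potentiation_is_100pct(self):
        p = fl.preset("air", seed=5, p_ss=1.0, a_ptp=0.0, noise_sd=0.0)
        res = fl.analyze_ltp(fl.simulate_experiment(p, fl.build_ltp_experiment()))
        assert res.ltp_magnitude == pytest.approx(100.0, abs=1e-6)

    def test_closed_form_window_average(self):
        p = fl.preset("air", seed=5, p_ss=2.0, tau_ltp=5.0, noise_sd=0.0)
        res = fl.analyze_ltp(fl.simulate_experiment(p, fl.build_ltp_experiment()))
        t = np.linspace(44, 59, 30001)
        target = 100 * np.mean(1 + (p.p_ss - 1) * (1 - np.exp(-t / p.tau_ltp))
                               + p.a_ptp * np.exp(-t / p.tau_ptp))
        assert res.ltp_magnitude == pytest.approx(target, rel=0.02)

    def test_baseline_normalization_is_exact(self):
        p = fl.preset("air", seed=6)
        rec = fl.simulate_experiment(p, fl.build_ltp_experiment())
        res = fl.analyze_ltp(rec)
        pre = res.timecourse_t < 0
        # minute-binned baseline values average to 100% by construction
        assert np.mean(res.timecourse_slope[pre]) == pytest.approx(100.0, abs=1e-9)

    def test_hyperoxia_ltp_larger_at_matched_seed(self):
        mags = {}
        for cond in ("air", "hyperoxia"):
            p = fl.preset(cond, seed=41)
            mags[cond] = fl.analyze_ltp(
                fl.simulate_experiment(p, fl.build_ltp_experiment())).ltp_magnitude
        assert mags["hyperoxia"] > mags["air"]

    def test_noisy_recovery_across_seeds(self):
        vals = []
        for seed in range(20):
            p = fl.preset("air", seed=500 + seed)
            vals.append(fl.analyze_ltp(
                fl.simulate_experiment(p, fl.build_ltp_experiment())).ltp_magnitude)
        t = np.linspace(44, 59, 30001)
        p0 = fl.preset("air")
        target = 100 * np.mean(1 + (p0.p_ss - 1) * (1 - np.exp(-t / p0.tau_ltp))
                               + p0.a_ptp * np.exp(-t / p0.tau_ptp))
        assert np.mean(vals) == pytest.approx(target, rel=0.05)

    def test_window_beyond_recording_rejected(self):
        p = fl.preset("air", seed=5, noise_sd=0.0)
        rec = fl.simulate_experiment(
            p, fl.build_ltp_experiment(followup_min=30.0))
        with pytest.raises(AnalysisError, match="window"):
            fl.analyze_ltp(rec)


class TestTetanusDepolarization:
    def test_flat_traces_give_zero(self):
        sweeps = [fl.Sweep(samples=np.zeros(1500), stimulus_times=[20.0],
                           meta={"burst_index": b}) for b in range(10)]
        res = fl.tetanus_depolarization(sweeps)
        assert res.per_burst_auc == [0.0] * 10
        assert res.mean_auc == 0.0

    def test_missing_burst_listed(self):
        sweeps = [fl.Sweep(samples=np.zeros(1500), stimulus_times=[20.0],
                           meta={"burst_index": b}) for b in (0, 1, 2, 4, 5, 6, 7, 8, 9)]
        with pytest.raises(AnalysisError, match=r"\[3\]"):
            fl.tetanus_depolarization(sweeps)

    def test_syn_gain_doubling_doubles_auc(self, air_quiet):
        rec1 = fl.simulate_experiment(air_quiet, fl.build_tbs())
        p2 = dataclasses.replace(air_quiet, syn_gain=2 * air_quiet.syn_gain)
        rec2 = fl.simulate_experiment(p2, fl.build_tbs())
        a1 = fl.tetanus_depolarization(list(rec1)).mean_auc
        a2 = fl.tetanus_depolarization(list(rec2)).mean_auc
        assert a2 == pytest.approx(2 * a1, rel=0.01)

    def test_hyperoxia_auc_and_mcbi_larger(self):
        res = {}
        for cond in ("air", "hyperoxia"):
            p = fl.preset(cond, seed=61)
            rec = fl.simulate_experiment(p, fl.build_tbs())
            res[cond] = (fl.tetanus_depolarization(list(rec)).mean_auc,
                         fl.mean_mcbi(list(rec)))
        assert res["hyperoxia"][0] > res["air"][0]
        assert res["hyperoxia"][1] > res["air"][1]
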