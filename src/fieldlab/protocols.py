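"""Experiment-level analyses: input-output curves, paired-pulse ratio,
baseline-stability screening, theta-burst construction, LTP magnitude, and
postsynaptic depolarization during the tetanus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .config import AnalysisConfig
from .core import Recording, StimulusProtocol, Sweep
from .errors import AnalysisError, ValidationError
from .metrics import (
    baseline_voltage,
    compute_mcbi,
    detect_stimulus_onset,
    measure_auc,
    measure_fiber_volley,
    measure_initial_slope,
)

# ---------------------------------------------------------------------------
# protocol builders
# ---------------------------------------------------------------------------

def build_tbs() -> StimulusProtocol:
    """Weak theta-burst stimulation: 5 pulses at 100 Hz per burst, 10 bursts
    at 200 ms intervals — 50 pulses in one bout."""
    pulse_times = [200.0 * burst + 10.0 * p for burst in range(10) for p in range(5)]
    return StimulusProtocol(kind="tbs", pulse_times=pulse_times,
                            sweep_duration=150.0)


def build_io_ramp(i_max: float = 320.0, step: float = 10.0,
                  sweeps_per_intensity: int = 6) -> StimulusProtocol:
    """Input-output ramp: intensities 0..i_max in ``step`` µA increments,
    ``sweeps_per_intensity`` sweeps each, delivered at 0.1 Hz."""
    levels = np.arange(0.0, i_max + step / 2, step)
    intensities = [float(i) for i in levels for _ in range(sweeps_per_intensity)]
    return StimulusProtocol(kind="io_ramp", intensities=intensities,
                            n_sweeps=len(intensities))


def build_paired_pulse(isi: float = 50.0, n_sweeps: int = 12,
                       stim_onset: float = 20.0) -> StimulusProtocol:
    """Paired pulses at a 50 ms inter-stimulus interval."""
    return StimulusProtocol(kind="paired_pulse", isi=isi, n_sweeps=n_sweeps,
                            pulse_times=[stim_onset, stim_onset + isi],
                            sweep_duration=150.0)


def build_baseline(duration_min: float = 20.0,
                   inter_sweep_interval: float = 10.0) -> StimulusProtocol:
    """0.1 Hz baseline train of single pulses."""
    n = int(round(duration_min * 60.0 / inter_sweep_interval))
    return StimulusProtocol(kind="baseline", n_sweeps=n,
                            inter_sweep_interval=inter_sweep_interval)


def build_ltp_experiment(baseline_min: float = 20.0,
                         followup_min: float = 60.0) -> StimulusProtocol:
    """Full LTP experiment: baseline, one TBS bout, post-tetanus follow-up."""
    return StimulusProtocol(kind="ltp_experiment",
                            meta={"baseline_min": baseline_min,
                                  "followup_min": followup_min})


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class IOCurve:
    intensities: np.ndarray        # µA, strictly increasing
    mean_slope: np.ndarray         # mV/ms per intensity
    mean_fv: np.ndarray            # mV per intensity
    per_sweep_slope: dict[float, list[float]]
    per_sweep_fv: dict[float, list[float]]
    underpopulated: list[float] = field(default_factory=list)

    @property
    def max_slope(self) -> float:
        """Mean slope at the maximal stimulus intensity."""
        return float(self.mean_slope[-1])

    @property
    def max_fv(self) -> float:
        return float(self.mean_fv[-1])

    def half_max_intensity(self) -> float:
        """Ramp intensity whose mean slope is nearest 50% of the I/O maximum."""
        target = 0.5 * float(np.max(self.mean_slope))
        return float(self.intensities[int(np.argmin(np.abs(self.mean_slope - target)))])


@dataclass
class PPRResult:
    slope1: float                  # mV/ms, mean over sweeps
    slope2: float
    ppr: float                     # mean of per-sweep slope2/slope1
    isi: float                     # ms
    per_sweep_ppr: list[float] = field(default_factory=list)
    subtraction: str = "monoexponential tail fit"


@dataclass
class LTPResult:
    timecourse_t: np.ndarray       # min, bin centers (TBS at 0)
    timecourse_slope: np.ndarray   # % of baseline
    baseline_mean_slope: float     # mV/ms
    ltp_magnitude: float           # % of baseline over the analysis window
    analysis_window: tuple[float, float]
    baseline_fv: float             # mV
    included: bool
    variance_pct: float
    reason: str = ""


@dataclass
class AUCResult:
    per_burst_auc: list[float]     # mV·ms
    mean_auc: float


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def _measure_one(sweep: Sweep, cfg: AnalysisConfig):
    from .metrics import SlopeFit

    w = cfg.windows
    stim = detect_stimulus_onset(sweep, z_threshold=cfg.thresholds.detect_z)
    base = baseline_voltage(sweep, stim, gap=w.baseline_gap)
    fv = measure_fiber_volley(
        sweep, (stim + w.fv_window[0], stim + w.fv_window[1]), baseline=base)
    try:
        fit = measure_initial_slope(
            sweep, (stim + w.epsp_window[0],
                    min(stim + w.epsp_window[1], sweep.duration)),
            rise_fraction=w.rise_fraction, baseline=base)
    except ValidationError:
        # subthreshold response (e.g. zero stimulus intensity): no measurable
        # fEPSP, slope recorded as 0
        fit = SlopeFit(slope=0.0, signed_slope=0.0, fit_start=float("nan"),
                       fit_stop=float("nan"), n_points=0,
                       peak_time=float("nan"), peak_amplitude=0.0)
    return stim, base, fv, fit


def analyze_io(recording: Recording, config: AnalysisConfig | None = None,
               expected_per_intensity: int = 6) -> IOCurve:
    """Per-intensity mean initial slope and fiber-volley amplitude.

    Intensities with fewer than ``expected_per_intensity`` sweeps are flagged;
    intensities with no usable sweeps are omitted with a warning.
    """
    cfg = config or AnalysisConfig()
    slopes: dict[float, list[float]] = {}
    fvs: dict[float, list[float]] = {}
    for sweep in recording:
        inten = float(sweep.stimulus_intensity)
        _, _, fv, fit = _measure_one(sweep, cfg)
        slopes.setdefault(inten, []).append(fit.slope)
        fvs.setdefault(inten, []).append(fv)
    if not slopes:
        raise AnalysisError("recording contains no sweeps")
    levels = sorted(slopes)
    under = [i for i in levels if len(slopes[i]) < expected_per_intensity]
    if under:
        warnings.warn(f"intensities with <{expected_per_intensity} sweeps: {under}")
    return IOCurve(
        intensities=np.array(levels),
        mean_slope=np.array([float(np.mean(slopes[i])) for i in levels]),
        mean_fv=np.array([float(np.mean(fvs[i])) for i in levels]),
        per_sweep_slope=slopes,
        per_sweep_fv=fvs,
        underpopulated=under,
    )


def _monoexp(t, a, tau):
    return a * np.exp(-t / tau)


def _tail_subtraction(sweep: Sweep, cfg: AnalysisConfig, stim1: float,
                      stim2: float, base: float, peak_time: float) -> np.ndarray:
    """Extrapolated tail of the first response as a full-length array.

    A mono-exponential is fitted to the deviation (baseline − V) on the first
    response's decay, from shortly after its peak to just before the second
    stimulus, then extrapolated over the remainder of the sweep.
    """
    dt = sweep.sample_interval
    t = sweep.time
    i_fit_lo = sweep.index_at(peak_time + 5.0)
    i_fit_hi = sweep.index_at(stim2 - 0.5)
    if i_fit_hi - i_fit_lo < 5:
        raise AnalysisError(
            f"sweep {sweep.sweep_index}: responses overlap too much for tail fit")
    seg_t = t[i_fit_lo:i_fit_hi] - peak_time
    seg_d = base - sweep.samples[i_fit_lo:i_fit_hi]
    a0 = max(float(seg_d[0]), 1e-6)
    tau0 = 20.0
    try:
        (a, tau), _ = curve_fit(_monoexp, seg_t, seg_d, p0=(a0, tau0),
                                bounds=([0.0, 1.0], [np.inf, 500.0]), maxfev=2000)
    except RuntimeError as exc:  # pragma: no cover - pathological traces
        raise AnalysisError(
            f"sweep {sweep.sweep_index}: tail fit failed ({exc})") from exc
    tail = np.zeros_like(t)
    m = t >= peak_time
    tail[m] = -_monoexp(t[m] - peak_time, a, tau)  # tail in voltage terms
    return tail


def analyze_ppr(recording: Recording, config: AnalysisConfig | None = None) -> PPRResult:
    """Paired-pulse ratio: second fEPSP slope / first fEPSP slope.

    The second slope is measured after subtracting the extrapolated
    mono-exponential tail of the first response.
    """
    cfg = config or AnalysisConfig()
    w = cfg.windows
    s1s, s2s, pprs = [], [], []
    isi = recording.protocol.isi if recording.protocol else 50.0
    for sweep in recording:
        if len(sweep.stimulus_times) < 2:
            raise AnalysisError(
                f"sweep {sweep.sweep_index}: paired-pulse sweep needs 2 stimuli")
        stim1, stim2 = sweep.stimulus_times[:2]
        base = baseline_voltage(sweep, stim1, gap=w.baseline_gap)
        fit1 = measure_initial_slope(
            sweep, (stim1 + w.epsp_window[0], min(stim1 + w.epsp_window[1], stim2)),
            rise_fraction=w.rise_fraction, baseline=base)
        tail = _tail_subtraction(sweep, cfg, stim1, stim2, base, fit1.peak_time)
        fit2 = measure_initial_slope(
            sweep, (stim2 + w.epsp_window[0],
                    min(stim2 + w.epsp_window[1], sweep.duration)),
            rise_fraction=w.rise_fraction, baseline=base, subtract=tail)
        if fit1.slope <= 0:
            raise AnalysisError(f"sweep {sweep.sweep_index}: first slope is zero")
        s1s.append(fit1.slope)
        s2s.append(fit2.slope)
        pprs.append(fit2.slope / fit1.slope)
    slope1, slope2 = float(np.mean(s1s)), float(np.mean(s2s))
    # ratio of mean slopes: per-sweep ratios are kept for inspection, but the
    # reported PPR divides the averaged second slope by the averaged first,
    # which is unbiased under symmetric per-sweep measurement noise
    return PPRResult(slope1=slope1, slope2=slope2, ppr=slope2 / slope1,
                     isi=float(isi), per_sweep_ppr=pprs)


def check_baseline_stability(times_min, slopes, limit_pct: float = 8.0,
                             bin_width_min: float = 1.0) -> tuple[bool, float]:
    """Baseline inclusion rule: CV of 1-min binned mean slopes ≤ limit.

    ``variance_pct`` is 100 × (sd of the per-bin mean slopes about the overall
    baseline mean, ddof 0) / overall mean. Returns (included, variance_pct).
    """
    t = np.asarray(times_min, dtype=float)
    s = np.asarray(slopes, dtype=float)
    if s.size < 10:
        raise ValidationError("need at least 10 baseline sweeps")
    overall = float(s.mean())
    if overall <= 0:
        raise ValidationError("baseline mean slope must be > 0")
    bins = np.floor((t - t.min()) / bin_width_min).astype(int)
    if np.unique(bins).size < 2:
        raise ValidationError("baseline spans fewer than two bins")
    bin_means = np.array([s[bins == b].mean() for b in np.unique(bins)])
    variance_pct = 100.0 * float(np.sqrt(np.mean((bin_means - overall) ** 2))) / overall
    return bool(variance_pct <= limit_pct), variance_pct


def _split_ltp(recording: Recording):
    baseline, tbs, followup = [], [], []
    for sweep in recording:
        phase = sweep.meta.get("phase")
        if phase == "tbs":
            tbs.append(sweep)
        elif phase == "followup" or (phase is None and sweep.t_acquired > 0):
            followup.append(sweep)
        else:
            baseline.append(sweep)
    return baseline, tbs, followup


def analyze_ltp(recording: Recording, config: AnalysisConfig | None = None) -> LTPResult:
    """LTP magnitude as % of the pre-tetanus baseline slope.

    Slopes are normalized so the baseline-period mean is exactly 100%, binned
    per minute relative to TBS onset (baseline at negative times), and the
    LTP magnitude is the mean normalized slope over the analysis window
    (default [44, 59] min post-TBS). The mean baseline fiber-volley amplitude
    is reported for the cross-group stimulus-strength control.
    """
    cfg = config or AnalysisConfig()
    base_sw, _, follow_sw = _split_ltp(recording)
    if not base_sw or not follow_sw:
        raise AnalysisError("LTP recording needs baseline and follow-up sweeps")
    win = cfg.windows.ltp_window
    t_end = max(s.t_acquired for s in follow_sw)
    if win[1] > t_end + 1e-9:
        raise AnalysisError(
            f"analysis window {win} extends beyond recording end ({t_end:.1f} min)")

    base_t = np.array([s.t_acquired for s in base_sw])
    base_meas = [_measure_one(s, cfg) for s in base_sw]
    base_slopes = np.array([m[3].slope for m in base_meas])
    base_fv = float(np.mean([m[2] for m in base_meas]))
    included, var_pct = check_baseline_stability(
        base_t, base_slopes, limit_pct=cfg.thresholds.baseline_variance_limit)

    follow_t = np.array([s.t_acquired for s in follow_sw])
    follow_slopes = np.array([_measure_one(s, cfg)[3].slope for s in follow_sw])

    baseline_mean = float(base_slopes.mean())
    norm_base = 100.0 * base_slopes / baseline_mean
    norm_follow = 100.0 * follow_slopes / baseline_mean

    all_t = np.concatenate([base_t, follow_t])
    all_norm = np.concatenate([norm_base, norm_follow])
    bins = np.floor(all_t).astype(int)
    uniq = np.unique(bins)
    tc_t = np.array([b + 0.5 for b in uniq])
    tc_v = np.array([all_norm[bins == b].mean() for b in uniq])

    in_win = (follow_t >= win[0]) & (follow_t <= win[1])
    magnitude = float(norm_follow[in_win].mean())
    return LTPResult(
        timecourse_t=tc_t,
        timecourse_slope=tc_v,
        baseline_mean_slope=baseline_mean,
        ltp_magnitude=magnitude,
        analysis_window=win,
        baseline_fv=base_fv,
        included=included,
        variance_pct=var_pct,
        reason="" if included else
        f"baseline variance {var_pct:.1f}% exceeds "
        f"{cfg.thresholds.baseline_variance_limit:.0f}% limit",
    )


def tetanus_depolarization(tbs_sweeps: list[Sweep],
                           config: AnalysisConfig | None = None,
                           n_bursts: int = 10) -> AUCResult:
    """Postsynaptic depolarization during the tetanus: per-burst rectified AUC
    over [burst onset, onset + 100 ms], and its mean across bursts."""
    cfg = config or AnalysisConfig()
    w = cfg.windows
    present = {s.meta.get("burst_index", i) for i, s in enumerate(tbs_sweeps)}
    missing = sorted(set(range(n_bursts)) - present)
    if missing:
        raise AnalysisError(f"missing theta bursts: indices {missing}")
    aucs = []
    for sweep in tbs_sweeps:
        if not sweep.stimulus_times:
            raise AnalysisError(
                f"sweep {sweep.sweep_index}: burst onset annotation required")
        onset = sweep.stimulus_times[0]
        base = baseline_voltage(sweep, onset, gap=w.baseline_gap)
        dur = min(w.auc_duration, sweep.duration - onset - sweep.sample_interval)
        aucs.append(measure_auc(sweep, onset, dur, baseline=base))
    return AUCResult(per_burst_auc=aucs, mean_auc=float(np.mean(aucs)))


def mean_mcbi(tbs_sweeps: list[Sweep], config: AnalysisConfig | None = None) -> float:
    """Mean modified Coastline Burst Index across the theta-burst sweeps."""
    cfg = config or AnalysisConfig()
    lo, hi = cfg.windows.mcbi_window
    vals = []
    for sweep in tbs_sweeps:
        hi_eff = min(hi, sweep.duration - sweep.sample_interval)
        vals.append(compute_mcbi(sweep, (lo, hi_eff)).value)
    if not vals:
        raise AnalysisError("no theta-burst sweeps supplied")
    return float(np.mean(vals))
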