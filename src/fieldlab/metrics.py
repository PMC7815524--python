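"""Per-sweep measurements on extracellular field potentials.

Sign conventions: the fEPSP and fiber volley are negative-going deflections;
amplitudes are reported as non-negative magnitudes of the deviation below the
pre-stimulus baseline, and the initial slope is reported as a magnitude with
the fit region recorded. The depolarization AUC integrates the rectified
negativity max(0, baseline − V). All measurements are therefore invariant to
a constant voltage offset.

Baseline voltage is the mean over [0, stimulus onset − 2 ms].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .core import Sweep
from .errors import DetectionError, ValidationError

_ = AnalysisConfig  # default windows live in config; functions accept raw windows


def baseline_voltage(sweep: Sweep, stim_time: float, gap: float = 2.0) -> float:
    """Mean voltage over the pre-stimulus window [0, stim_time − gap]."""
    i_end = sweep.index_at(stim_time - gap)
    if i_end < 1:
        raise ValidationError("no pre-stimulus samples available for baseline")
    return float(sweep.samples[:i_end].mean())


def detect_stimulus_onset(sweep: Sweep, z_threshold: float = 6.0,
                          pre_window: float = 10.0) -> float:
    """Stimulus onset time in ms.

    Returns the first annotated stimulus time when present; otherwise the
    first sample whose deviation from the leading pre-window mean exceeds
    ``z_threshold`` pre-window standard deviations (resolution: one sample).
    """
    if sweep.stimulus_times:
        return float(sweep.stimulus_times[0])
    n_pre = max(int(round(pre_window / sweep.sample_interval)), 2)
    n_pre = min(n_pre, sweep.n_samples // 4)
    if n_pre < 2:
        raise DetectionError("sweep too short to estimate pre-stimulus noise")
    pre = sweep.samples[:n_pre]
    mu, sd = float(pre.mean()), float(pre.std())
    sd = max(sd, 1e-9)
    above = np.abs(sweep.samples - mu) > z_threshold * sd
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise DetectionError("no stimulus artifact found and no annotation present")
    return float(idx[0] * sweep.sample_interval)


def measure_fiber_volley(sweep: Sweep, window: tuple[float, float],
                         baseline: float | None = None,
                         stim_time: float | None = None) -> float:
    """Magnitude (mV, ≥0) of the most negative deviation from baseline in a window.

    ``window`` is absolute within-sweep time in ms.
    """
    lo, hi = window
    if lo < 0 or hi > sweep.duration or hi <= lo:
        raise ValidationError(f"fiber-volley window [{lo}, {hi}] outside sweep")
    if baseline is None:
        if stim_time is None:
            stim_time = detect_stimulus_onset(sweep)
        baseline = baseline_voltage(sweep, stim_time)
    i_lo, i_hi = sweep.index_at(lo), sweep.index_at(hi)
    seg = sweep.samples[i_lo:i_hi + 1]
    return float(max(0.0, baseline - seg.min()))


@dataclass
class SlopeFit:
    """Initial-slope measurement with its fit region recorded."""

    slope: float          # magnitude, mV/ms
    signed_slope: float   # raw fitted slope of V(t), mV/ms (negative-going)
    fit_start: float      # ms
    fit_stop: float       # ms
    n_points: int
    peak_time: float      # ms
    peak_amplitude: float  # mV, deviation magnitude at peak

    def __float__(self) -> float:
        return self.slope


def measure_initial_slope(
    sweep: Sweep,
    search_window: tuple[float, float],
    rise_fraction: tuple[float, float] = (0.2, 0.8),
    baseline: float | None = None,
    stim_time: float | None = None,
    subtract: np.ndarray | None = None,
    smooth_ms: float = 0.5,
) -> SlopeFit:
    """fEPSP initial slope: least-squares line over the 20–80% rising chord.

    The fEPSP peak is the most negative deviation from baseline inside the
    absolute ``search_window``; the fit uses the samples on the negative-going
    phase whose deviation lies between ``rise_fraction`` of the peak
    deviation. ``subtract`` (full-length array, mV) removes a known
    contaminating component — e.g. the extrapolated tail of a preceding
    response — before measuring.
    """
    lo, hi = search_window
    if lo < 0 or hi > sweep.duration or hi <= lo:
        raise ValidationError(f"fEPSP search window [{lo}, {hi}] outside sweep")
    v = sweep.samples if subtract is None else sweep.samples - subtract
    if baseline is None:
        if stim_time is None:
            stim_time = detect_stimulus_onset(sweep)
        i_end = sweep.index_at(stim_time - 2.0)
        if i_end < 1:
            raise ValidationError("no pre-stimulus samples available for baseline")
        baseline = float(v[:i_end].mean())
    i_lo, i_hi = sweep.index_at(lo), sweep.index_at(hi)
    dev = baseline - v[i_lo:i_hi + 1]        # positive-going deviation
    # peak and chord endpoints are located on a lightly smoothed copy so that
    # sample noise neither inflates the peak nor truncates the fit span; the
    # line itself is fitted to the raw samples
    def boxcar(x: np.ndarray, width_ms: float) -> np.ndarray:
        n = max(1, int(round(width_ms / sweep.sample_interval)))
        if n <= 1:
            return x
        return np.convolve(x, np.ones(n) / n, mode="same")

    dev_s = boxcar(dev, smooth_ms)        # fitted
    dev_det = boxcar(dev, 3 * smooth_ms)  # peak/crossing detection only
    i_pk = int(np.argmax(dev_det))
    # peak amplitude as a ±1 ms local average around the smoothed argmax:
    # immune to the upward bias a noisy pointwise maximum would add to the
    # chord thresholds
    half = max(1, int(round(1.0 / sweep.sample_interval)))
    peak = float(dev[max(0, i_pk - half):min(dev.size, i_pk + half + 1)].mean())
    f_lo, f_hi = rise_fraction
    rise = dev_det[:i_pk + 1]
    below_hi = np.flatnonzero(rise < f_hi * peak)
    j_hi = int(below_hi[-1]) if below_hi.size else 0
    below_lo = np.flatnonzero(rise[:j_hi + 1] < f_lo * peak)
    j_lo = int(below_lo[-1]) + 1 if below_lo.size else 0
    idx = np.arange(j_lo, j_hi + 1)
    if idx.size < 3:
        raise ValidationError(
            "fewer than 3 samples in the slope-fit region; a denser sampling "
            "rate (or wider rise_fraction band) is required")
    t_fit = (idx + i_lo) * sweep.sample_interval
    # fit on the smoothed deviation (sign restored): same chord, less noise
    slope, _ = np.polyfit(t_fit, -dev_s[idx] + baseline, 1)
    return SlopeFit(
        slope=abs(float(slope)),
        signed_slope=float(slope),
        fit_start=float(t_fit[0]),
        fit_stop=float(t_fit[-1]),
        n_points=int(idx.size),
        peak_time=float((i_pk + i_lo) * sweep.sample_interval),
        peak_amplitude=peak,
    )


def measure_auc(sweep: Sweep, start: float, duration: float = 100.0,
                baseline: float | None = None,
                stim_time: float | None = None) -> float:
    """Rectified depolarization area, mV·ms, over [start, start+duration].

    Trapezoidal integral of max(0, baseline − V(t)); baseline from the
    pre-stimulus mean.
    """
    stop = start + duration
    if start < 0 or stop > sweep.duration:
        raise ValidationError(
            f"AUC window [{start}, {stop}] exceeds sweep duration {sweep.duration}")
    if baseline is None:
        if stim_time is None:
            stim_time = detect_stimulus_onset(sweep)
        baseline = baseline_voltage(sweep, stim_time)
    i_lo, i_hi = sweep.index_at(start), sweep.index_at(stop)
    dev = np.maximum(0.0, baseline - sweep.samples[i_lo:i_hi + 1])
    return float(np.trapezoid(dev, dx=sweep.sample_interval))


@dataclass
class MCBIResult:
    value: float      # mV
    n_samples: int    # samples inside the window (count recorded, see note)

    def __float__(self) -> float:
        return self.value


def compute_mcbi(sweep: Sweep, window: tuple[float, float] = (25.0, 125.0)) -> MCBIResult:
    """Modified Coastline Burst Index: Σ |V_{x+1} − V_x| inside the window, mV.

    The sum runs over consecutive sample pairs whose samples both lie inside
    the absolute window [lo, hi]; the number of samples used is recorded.
    """
    lo, hi = window
    if lo < 0 or hi > sweep.duration:
        raise ValidationError(f"mCBI window [{lo}, {hi}] outside sweep")
    i_lo, i_hi = sweep.index_at(lo), sweep.index_at(hi)
    if i_hi - i_lo < 1:
        raise ValidationError("mCBI window must contain at least 2 samples")
    seg = sweep.samples[i_lo:i_hi + 1]
    # left-to-right accumulation: bit-identical to the defining elementwise sum
    total = 0.0
    for d in np.abs(np.diff(seg)).tolist():
        total += d
    return MCBIResult(value=total, n_samples=int(seg.size))


def normalize_metric(values, reference_mean: float) -> np.ndarray:
    """Express per-slice metric values relative to a reference group mean."""
    if reference_mean <= 0:
        raise ValidationError("reference_mean must be > 0")
    return np.asarray(values, dtype=float) / reference_mean


@dataclass
class SweepMeasures:
    """Standard per-sweep measurement bundle."""

    sweep_index: int
    t_acquired: float      # min
    intensity: float       # µA
    stim_time: float       # ms
    fv_amplitude: float    # mV
    epsp_slope: float      # mV/ms, magnitude
    epsp_amplitude: float  # mV
    auc: float             # mV·ms
    mcbi: float            # mV


def measure_sweep(sweep: Sweep, config: AnalysisConfig | None = None) -> SweepMeasures:
    """Apply the full measurement battery to one sweep."""
    cfg = config or AnalysisConfig()
    w = cfg.windows
    stim = detect_stimulus_onset(sweep, z_threshold=cfg.thresholds.detect_z)
    base = baseline_voltage(sweep, stim, gap=w.baseline_gap)
    fv = measure_fiber_volley(
        sweep, (stim + w.fv_window[0], stim + w.fv_window[1]), baseline=base)
    fit = measure_initial_slope(
        sweep, (stim + w.epsp_window[0], min(stim + w.epsp_window[1], sweep.duration)),
        rise_fraction=w.rise_fraction, baseline=base)
    auc_dur = min(w.auc_duration, sweep.duration - stim - sweep.sample_interval)
    auc = measure_auc(sweep, stim, auc_dur, baseline=base)
    m_lo, m_hi = w.mcbi_window
    m_hi = min(m_hi, sweep.duration - sweep.sample_interval)
    mcbi = compute_mcbi(sweep, (m_lo, m_hi)).value if m_hi > m_lo else float("nan")
    return SweepMeasures(
        sweep_index=sweep.sweep_index,
        t_acquired=sweep.t_acquired,
        intensity=sweep.stimulus_intensity,
        stim_time=stim,
        fv_amplitude=fv,
        epsp_slope=fit.slope,
        epsp_amplitude=fit.peak_amplitude,
        auc=auc,
        mcbi=mcbi,
    )
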