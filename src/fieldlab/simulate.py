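"""Seeded generative model of extracellular field-potential sweeps.

The model is phenomenological, not biophysical. Each stimulus pulse at time
``t_k`` contributes, on top of a flat baseline:

* a brief positive stimulus artifact (fast exponential);
* a presynaptic fiber volley: a negative alpha function whose amplitude
  follows a Hill recruitment curve of stimulus current,
  ``A_fv(I) = fv_max · I^h / (I^h + i_half^h)``;
* a field EPSP: a normalized dual-exponential (tau_rise, tau_decay) whose
  peak is ``−syn_gain · A_fv · F_k · P``, where ``F_k`` is short-term
  facilitation relative to the preceding pulse and ``P`` the long-term
  potentiation factor of the sweep;
* optionally, population spikes (brief negative alpha deflections) drawn on
  the falling phase of sufficiently large responses.

Facilitation is calibrated so that the paired response at a 50 ms interval is
exactly ``f50`` times the first: ``F = 1 + (f50 − 1)·exp(−(Δt − 50)/tau_f)``.
Potentiation after a tetanus at experiment time 0 follows
``P(t) = 1 + (p_ss − 1)(1 − e^{−t/tau_ltp}) + a_ptp·e^{−t/tau_ptp}`` (t in
minutes). Responses to successive pulses sum linearly; measurement noise is
i.i.d. Gaussian and slow drift is linear in experiment time.

Reproducibility: one seed per recording; each sweep gets an independent RNG
substream derived from ``(seed, sweep_index)``, so regenerating any sweep is
order-independent and bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import DEFAULT_SAMPLE_INTERVAL_MS, Recording, StimulusProtocol, Sweep
from .errors import ValidationError
from .protocols import (
    build_baseline,
    build_io_ramp,
    build_ltp_experiment,
    build_paired_pulse,
    build_tbs,
)

CONDITIONS = ("air", "hyperoxia")


@dataclass
class SimParams:
    """Generative parameters for synthetic field-potential sweeps.

    Amplitudes in mV, within-sweep times in ms, experiment times in minutes,
    currents in µA.
    """

    # fiber volley recruitment and shape
    fv_max: float = 0.275        # maximal fiber volley amplitude, mV
    i_half: float = 100.0        # half-recruitment current, µA
    hill: float = 2.0            # recruitment steepness
    fv_latency: float = 0.8      # stimulus → fiber volley onset, ms
    fv_tau: float = 0.4          # alpha-function time constant, ms
    # synaptic response
    syn_gain: float = 3.75       # fEPSP peak per mV of fiber volley
    epsp_latency: float = 3.0    # stimulus → fEPSP onset, ms
    tau_rise: float = 2.0        # ms
    tau_decay: float = 20.0      # ms
    # short-term plasticity
    f50: float = 1.5             # paired-pulse ratio at 50 ms
    tau_f: float = 50.0          # facilitation decay, ms
    # long-term plasticity
    p_ss: float = 1.34           # steady-state potentiation factor
    tau_ltp: float = 5.0         # min
    a_ptp: float = 0.8           # post-tetanic transient amplitude
    tau_ptp: float = 1.5         # min
    # population spikes
    popspike_rate: float = 0.0   # expected spikes per suprathreshold response
    popspike_amp: float = 0.5    # mV
    popspike_tau: float = 0.5    # ms
    popspike_threshold: float = 2.2  # response amplitude gate, mV
    # recording nuisances
    noise_sd: float = 0.05       # mV
    drift_rate: float = 0.0      # mV per min of experiment time
    artifact_amp: float = 5.0    # mV
    artifact_tau: float = 0.08   # ms
    stim_onset: float = 20.0     # default within-sweep stimulus time, ms
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL_MS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fv_tau", "tau_rise", "tau_decay", "tau_f", "tau_ltp",
                     "tau_ptp", "popspike_tau", "artifact_tau"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.tau_rise >= self.tau_decay:
            raise ValidationError("tau_rise must be < tau_decay (degenerate kinetics)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.hill <= 0:
            raise ValidationError("hill must be > 0")
        if self.i_half <= 0:
            raise ValidationError("i_half must be > 0")


#: Condition presets. The two presets differ only in fiber-volley ceiling,
#: synaptic gain, steady-state potentiation, and population-spike rate;
#: facilitation (f50) is identical by construction.
_PRESETS = {
    "air": dict(fv_max=0.275, syn_gain=3.75, p_ss=1.34, popspike_rate=0.0),
    "hyperoxia": dict(fv_max=0.495, syn_gain=4.50, p_ss=2.17, popspike_rate=2.0),
}


def preset(condition: str, **overrides) -> SimParams:
    """Return the generative parameter set for a study condition.

    ``"hyperoxia"`` has a larger fiber-volley ceiling, synaptic gain and LTP
    plateau than ``"air"``, plus population spikes during strong responses;
    everything else — notably the facilitation factor ``f50`` — is shared.
    """
    if condition not in _PRESETS:
        raise ValidationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return SimParams(**{**_PRESETS[condition], **overrides})


# ---------------------------------------------------------------------------
# closed-form ingredients
# ---------------------------------------------------------------------------

def fiber_volley_amplitude(params: SimParams, intensity: float) -> float:
    """Hill recruitment curve A_fv(I), mV."""
    if intensity <= 0:
        return 0.0
    ih = intensity ** params.hill
    return params.fv_max * ih / (ih + params.i_half ** params.hill)


def facilitation_factors(params: SimParams, pulse_times: Sequence[float]) -> np.ndarray:
    """Per-pulse facilitation F_k; F_1 = 1 and F at a 50 ms interval = f50."""
    times = np.asarray(pulse_times, dtype=float)
    f = np.ones(times.size)
    if params.f50 != 1.0:
        dt = np.diff(times)
        f[1:] = 1.0 + (params.f50 - 1.0) * np.exp(-(dt - 50.0) / params.tau_f)
    return f


def potentiation_factor(params: SimParams, t_min: float) -> float:
    """Long-term potentiation factor P(t), t in minutes after the tetanus.

    P(t ≤ 0) = 1; P(∞) = p_ss.
    """
    if t_min <= 0:
        return 1.0
    return (1.0
            + (params.p_ss - 1.0) * (1.0 - math.exp(-t_min / params.tau_ltp))
            + params.a_ptp * math.exp(-t_min / params.tau_ptp))


def _dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    return math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def epsp_shape(params: SimParams, s: np.ndarray) -> np.ndarray:
    """Normalized dual-exponential fEPSP shape (peak 1) vs time-from-onset s ≥ 0."""
    s = np.asarray(s, dtype=float)
    tpk = _dual_exp_peak_time(params.tau_rise, params.tau_decay)
    gmax = math.exp(-tpk / params.tau_decay) - math.exp(-tpk / params.tau_rise)
    out = np.zeros_like(s)
    m = s >= 0
    out[m] = (np.exp(-s[m] / params.tau_decay) - np.exp(-s[m] / params.tau_rise)) / gmax
    return out


def _alpha(s: np.ndarray, tau: float) -> np.ndarray:
    """Alpha function with unit peak at s = tau; zero for s < 0."""
    out = np.zeros_like(s)
    m = s >= 0
    x = s[m] / tau
    out[m] = x * np.exp(1.0 - x)
    return out


# ---------------------------------------------------------------------------
# sweep-level generation
# ---------------------------------------------------------------------------

def sweep_rng(params: SimParams, sweep_index: int) -> np.random.Generator:
    """Deterministic per-sweep RNG substream derived from (seed, sweep_index)."""
    return np.random.default_rng(np.random.SeedSequence((params.seed, sweep_index)))


def simulate_sweep(
    params: SimParams,
    intensity: float,
    pulse_times: Sequence[float],
    t_acquired: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    duration: float = 100.0,
    potentiation: float = 1.0,
    sweep_index: int = 0,
    meta: dict | None = None,
) -> Sweep:
    """Generate one sweep: artifact + fiber volley + fEPSP (+ spikes) + noise.

    ``potentiation`` multiplies the fEPSP of every pulse in the sweep (the
    caller evaluates P at the sweep's experiment time); drift adds a constant
    offset ``drift_rate · t_acquired``.
    """
    if intensity < 0:
        raise ValidationError("intensity must be >= 0")
    if rng is None:
        rng = sweep_rng(params, sweep_index)
    dt = params.sample_interval
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    v = np.full(n, params.drift_rate * t_acquired)

    pulse_times = list(pulse_times)
    a_fv = fiber_volley_amplitude(params, intensity)
    facil = facilitation_factors(params, pulse_times)
    tpk = _dual_exp_peak_time(params.tau_rise, params.tau_decay)

    peak_devs = []  # deterministic response amplitude per pulse, for spike gating
    for t_k, f_k in zip(pulse_times, facil):
        v += params.artifact_amp * np.where(
            t >= t_k, np.exp(-np.maximum(t - t_k, 0.0) / params.artifact_tau), 0.0)
        if a_fv > 0:
            v -= a_fv * _alpha(t - t_k - params.fv_latency, params.fv_tau)
            peak = params.syn_gain * a_fv * f_k * potentiation
            v -= peak * epsp_shape(params, t - t_k - params.epsp_latency)
        # amplitude of the summed trace at this pulse's fEPSP peak
        i_pk = int(round((t_k + params.epsp_latency + tpk) / dt))
        if i_pk < n:
            peak_devs.append((t_k, -v[i_pk] + params.drift_rate * t_acquired))
        else:
            peak_devs.append((t_k, 0.0))

    if params.popspike_rate > 0 and a_fv > 0:
        for t_k, dev in peak_devs:
            if dev <= params.popspike_threshold:
                continue
            n_sp = rng.poisson(params.popspike_rate)
            t_pk = t_k + params.epsp_latency + tpk
            for t_sp in rng.uniform(t_pk, t_pk + 10.0, size=n_sp):
                v -= params.popspike_amp * _alpha(t - t_sp, params.popspike_tau)

    if params.noise_sd > 0:
        v += rng.normal(0.0, params.noise_sd, size=n)

    return Sweep(
        samples=v,
        sample_interval=dt,
        stimulus_times=pulse_times,
        stimulus_intensity=intensity,
        sweep_index=sweep_index,
        t_acquired=t_acquired,
        meta=meta or {},
    )


# ---------------------------------------------------------------------------
# experiment-level generation
# ---------------------------------------------------------------------------

def _resolve_intensity(protocol: StimulusProtocol, params: SimParams, i: int) -> float:
    if protocol.intensities is None:
        # baseline stimulus strength targeting ~50% of the maximal response
        return params.i_half
    ints = protocol.intensities
    return float(ints[i]) if i < len(ints) else float(ints[-1])


def simulate_experiment(params: SimParams, protocol: StimulusProtocol) -> Recording:
    """Simulate a full recording for one protocol.

    Supported kinds: ``baseline``, ``io_ramp``, ``paired_pulse``, ``tbs``, and
    ``ltp_experiment`` (20 min baseline at 0.1 Hz, one theta-burst episode
    recorded burst-by-burst, then ≥60 min follow-up with the potentiation
    time course applied from tetanus onset).
    """
    kind = protocol.kind
    sweeps: list[Sweep] = []

    def add(idx, intensity, pulses, t_acq, duration, pot=1.0, **meta):
        sweeps.append(simulate_sweep(
            params, intensity, pulses, t_acq,
            rng=sweep_rng(params, idx), duration=duration,
            potentiation=pot, sweep_index=idx, meta=meta))

    isv_min = protocol.inter_sweep_interval / 60.0

    if kind in ("baseline", "io_ramp", "paired_pulse"):
        if protocol.n_sweeps is None or protocol.n_sweeps < 1:
            raise ValidationError(f"{kind} protocol needs n_sweeps >= 1")
        duration = protocol.sweep_duration or (150.0 if kind == "paired_pulse" else 100.0)
        for i in range(protocol.n_sweeps):
            intensity = _resolve_intensity(protocol, params, i)
            pulses = list(protocol.pulse_times) or [params.stim_onset]
            add(i, intensity, pulses, i * isv_min, duration)
        return Recording(sweeps=sweeps, protocol=protocol)

    if kind == "tbs":
        return Recording(
            sweeps=_tbs_sweeps(params, protocol, start_index=0, t_acq=0.0),
            protocol=protocol)

    if kind == "ltp_experiment":
        baseline_min = protocol.meta.get("baseline_min", 20.0)
        followup_min = protocol.meta.get("followup_min", 60.0)
        n_base = int(round(baseline_min * 60.0 / protocol.inter_sweep_interval))
        n_follow = int(round(followup_min * 60.0 / protocol.inter_sweep_interval))
        duration = protocol.sweep_duration or 100.0
        intensity = _resolve_intensity(protocol, params, 0)
        pulses = list(protocol.pulse_times) or [params.stim_onset]
        idx = 0
        for i in range(n_base):
            add(idx, intensity, pulses, -baseline_min + i * isv_min, duration,
                phase="baseline")
            idx += 1
        tbs_sw = _tbs_sweeps(params, build_tbs(), start_index=idx, t_acq=0.0,
                             intensity=intensity)
        sweeps.extend(tbs_sw)
        idx += len(tbs_sw)
        for i in range(n_follow):
            t_acq = (i + 1) * isv_min
            add(idx, intensity, pulses, t_acq, duration,
                pot=potentiation_factor(params, t_acq), phase="followup")
            idx += 1
        return Recording(sweeps=sweeps, protocol=protocol)

    raise ValidationError(f"unsupported protocol kind {kind!r}")


def _tbs_sweeps(params: SimParams, tbs: StimulusProtocol, start_index: int,
                t_acq: float, intensity: float | None = None) -> list[Sweep]:
    """One sweep per theta burst, pulses offset to the configured stimulus onset."""
    if intensity is None:
        intensity = params.i_half
    times = np.asarray(tbs.pulse_times, dtype=float)
    burst_starts = sorted(set(np.floor(times / 200.0) * 200.0))
    out = []
    for b, t0 in enumerate(burst_starts):
        in_burst = times[(times >= t0) & (times < t0 + 200.0)] - t0
        pulses = [params.stim_onset + float(x) for x in in_burst]
        out.append(simulate_sweep(
            params, intensity, pulses, t_acq,
            rng=sweep_rng(params, start_index + b),
            duration=tbs.sweep_duration or 150.0,
            sweep_index=start_index + b,
            meta={"phase": "tbs", "burst_index": b}))
    return out


__all__ = [
    "SimParams", "preset", "simulate_sweep", "simulate_experiment",
    "fiber_volley_amplitude", "facilitation_factors", "potentiation_factor",
    "epsp_shape", "sweep_rng", "CONDITIONS",
    "build_baseline", "build_io_ramp", "build_paired_pulse",
    "build_ltp_experiment", "build_tbs", "replace",
]
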