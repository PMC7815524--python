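# Methods

## Scope and conventions

All quantities use mV (voltage), ms (time within a sweep), µA (stimulus
current) and minutes (experiment time). Sweeps are sampled at 10 kHz by
default (0.1 ms/sample). Time within a sweep is zero at the first sample;
the simulator places the stimulus at 20 ms so that a coastline window
"beginning 5 ms after the stimulus artifact" starts at 25 ms. The fEPSP and
fiber volley are negative-going; all amplitudes are reported as magnitudes
of the deviation below the pre-stimulus baseline, defined as the mean
voltage over [0, stimulus onset − 2 ms]. Every measurement is therefore
invariant to a constant voltage offset.

## Generative model

A sweep is the sum of independent components, evaluated in closed form on
the sample grid:

```
V(t) = drift_rate·t_acq + Σ_k [ artifact_k(t) + FV_k(t) + fEPSP_k(t) ]
       + popspikes(t) + ε(t)
```

per stimulus pulse k at time t_k:

- **Artifact**: `artifact_amp · e^{−(t−t_k)/artifact_tau}` for t ≥ t_k
  (5 mV, τ = 0.08 ms). Positive-going, so it never contaminates the
  negative-deviation measures; narrow enough to have decayed to <0.1 % of
  the smallest fiber volley by the fiber-volley window.
- **Fiber volley**: negative alpha function `−A_fv·x·e^{1−x}`,
  `x = (t − t_k − fv_latency)/fv_tau` (latency 0.8 ms, τ = 0.4 ms), with
  Hill recruitment `A_fv(I) = fv_max · I^h/(I^h + i_half^h)`
  (h = 2, i_half = 100 µA). The FV peak falls on an exact sample
  (21.2 ms), so noise-free measurement recovers `A_fv` to <0.1 %.
- **fEPSP**: normalized dual exponential (τ_rise 2 ms, τ_decay 20 ms,
  onset latency 3 ms) with peak `−S·A_fv·F_k·P`. `S` (`syn_gain`) is the
  fEPSP peak per mV of fiber volley.
- **Facilitation**: `F_k = 1 + (f50 − 1)·e^{−(Δt−50)/tau_f}` with
  Δt the interval to the previous pulse (τ_f = 50 ms). By construction
  F(Δt = 50 ms) = f50 exactly and F → 1 as Δt → ∞; the same kernel acts
  within paired-pulse sweeps and within theta bursts (Δt = 10 ms), and
  responses to successive pulses sum linearly.
- **Potentiation**: after the tetanus,
  `P(t) = 1 + (p_ss − 1)(1 − e^{−t/τ_LTP}) + a_PTP·e^{−t/τ_PTP}`
  (τ_LTP = 5 min, a_PTP = 0.8, τ_PTP = 1.5 min); P = 1 before and during
  the tetanus. The steady state of the normalized slope is `p_ss`.
- **Population spikes**: when the deterministic response amplitude of a
  pulse exceeds 2.2 mV and the condition's `popspike_rate` is nonzero, a
  Poisson(rate) number of brief negative alpha deflections (0.5 mV,
  τ = 0.5 ms) is placed uniformly on the 10 ms after the fEPSP peak. The
  amplitude gate means spikes appear during theta-burst summation in the
  hyperoxia preset but not in single-pulse I/O or paired-pulse responses.
- **Noise and drift**: i.i.d. Gaussian ε (σ = 0.05 mV) and a linear
  offset drift in experiment time (0 by default). Because all metrics are
  baseline-subtracted, additive drift is deliberately benign; baseline
  instability screening is exercised with constructed slope series instead.

Reproducibility: each sweep draws from an RNG substream seeded by
`(seed, sweep_index)`, so recordings are bit-identical across reruns and
independent of generation order.

### Condition presets

`air` and `hyperoxia` share every kinetic constant and differ only in four
parameters:

| parameter | air | hyperoxia | role |
|---|---|---|---|
| fv_max (mV) | 0.275 | 0.495 | axonal recruitment ceiling |
| syn_gain | 3.75 | 4.50 | synaptic strength per mV of FV |
| p_ss | 1.34 | 2.17 | LTP plateau (× baseline) |
| popspike_rate | 0 | 2.0 | spikes per suprathreshold response |

The numbers are calibrated once so that noise-free analysis of the presets
returns a maximal I/O slope of ≈0.31 / 0.67 mV/ms, a maximal fiber volley
of ≈0.25 / 0.45 mV, and an LTP magnitude of ≈134 % / 217 % — values typical
of control vs hyperexcitable CA3–CA1 preparations. The calibration uses the
20–80 % chord factor of the dual exponential (0.330 /ms), i.e.
`syn_gain = slope / (0.330 · A_fv(320))`. Facilitation (f50 = 1.5) is
identical in both presets, so any measured group difference in PPR is a
false positive by construction.

## Measurement procedures

- **Stimulus onset**: annotated time when present, else the first sample
  deviating more than 6 pre-stimulus SDs from the pre-stimulus mean.
- **Initial slope**: the deviation trace is smoothed with two boxcars —
  0.5 ms for fitting, 1.5 ms for peak/chord detection. The peak amplitude is
  the raw deviation averaged over ±1 ms around the smoothed argmax (a local
  average, not a pointwise max, to avoid noise-inflated peaks biasing the
  chord thresholds). Chord endpoints are the last crossings of 20 % and
  80 % of the peak walking back from the peak; a least-squares line is
  fitted to the 0.5 ms-smoothed samples in that span and reported as a
  magnitude with the fit region recorded. Fewer than 3 samples in the span
  is an error asking for denser sampling.
- **Fiber volley**: most negative deviation in [onset+0.5, onset+2.5] ms
  (before the 3 ms fEPSP latency).
- **PPR**: second-pulse slope measured after subtracting the first
  response's tail, extrapolated by a mono-exponential fitted from 5 ms after
  the first peak to 0.5 ms before the second stimulus. The reported PPR is
  the ratio of mean slopes (mean slope 2 / mean slope 1), which is unbiased
  under symmetric per-sweep noise; per-sweep ratios are retained.
- **AUC**: trapezoidal integral of max(0, baseline − V) over
  [burst onset, +100 ms]; per theta burst, then averaged.
- **mCBI**: left-to-right accumulation of |V_{x+1} − V_x| over the window
  (default [25, 125] ms; the sample count actually used is recorded). The
  explicit sequential sum makes the value bit-identical to the defining
  elementwise loop.
- **Baseline inclusion**: the experiment is kept iff
  100 · RMS(1-min binned mean slopes − overall mean)/overall mean ≤ 8 %.
- **LTP**: slopes normalized so the 20-min baseline mean is exactly 100 %;
  timecourse binned per minute around TBS onset (baseline at negative
  times); magnitude = mean normalized slope over [44, 59] min post-TBS
  (window configurable; the upper bound is what defines "the last 5 min"
  here and both bounds are config options).
- **Statistics**: Welch's t from summary statistics
  `t = (m_a−m_b)/√(se_a²+se_b²)` with Welch–Satterthwaite df, so published
  n/mean±SE summaries are first-class inputs. Grubbs screening is
  two-sided, single-pass, one outlier maximum per group per metric, using
  the t-quantile critical value. Power uses the noncentral t. With zero
  variance in both groups and equal means, p = 1 by convention.

## Problem sizes

Default experiment sizes are the standard ones for this preparation: I/O
ramps of 33 intensities (0–320 µA, 10 µA steps) × 6 sweeps; 12 paired-pulse
sweeps at 50 ms; LTP experiments of 120 baseline sweeps (20 min at 0.1 Hz),
one 10-burst weak theta-burst bout (5 pulses at 100 Hz per burst, bursts at
200 ms), and 360 follow-up sweeps (60 min); cohorts of 6 slices per
condition. The test suite and the acceptance script use these sizes
directly; ensemble checks use 20 seeds/cohorts.

## Design choices where the field leaves room

- Slope window 20–80 % of the rising phase: avoids fiber-volley
  contamination near onset and curvature near the peak.
- PPR tail subtraction (mono-exponential): at 50 ms the first fEPSP retains
  ~12 % of its peak; without subtraction the PPR would be biased toward 1.
- AUC as rectified depolarizing deviation: reported as a positive area.
- mCBI window defaults to the [25, 125] ms of its defining sum even though
  repetitive spiking concentrates at 25–70 ms; both are configuration
  options.
- Baseline stimulus strength "~50 % of maximal": operationalized as the
  ramp intensity whose mean slope is nearest 50 % of the I/O maximum
  (`IOCurve.half_max_intensity`); the simulator's default intensity for
  baseline protocols is `i_half`, which realizes the same target exactly.
- The cohort runner gives every slice the same preset with a distinct
  derived seed: within-group variance is measurement noise only.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume — saturating
recruitment, linear summation, calibrated facilitation and potentiation,
population spikes, stationary Gaussian noise, offset drift. It does not
model biophysics (no conductances, no GABAergic circuit, no volume
conduction), non-stationary or correlated noise, electrode drift in
sensitivity, inter-slice biological variability, or spike-waveform
diversity. Passing tests therefore validate the measurement chain and its
conventions, not any claim about real tissue.

## Known limitations

- Population spikes land on the fEPSP decay; when large summated responses
  spike heavily (hyperoxia theta bursts and strongly potentiated follow-up
  sweeps), the smoothed peak that anchors the slope chord can be captured
  by a spike, attenuating measured slopes by ~10 %. The hyperoxia cohort
  therefore prints an LTP magnitude of ~190–195 % against a generative
  plateau of 217 % — the same kind of contamination real spiking slices
  produce. Spike-free recovery (air-type parameters) is accurate to <1 %.
- Slope measurements carry a small amplitude-dependent noise bias (smaller
  responses are measured with slightly larger relative error), which can
  shift cross-group PPR comparisons by a few percent when response sizes
  differ; at the default group size this occasionally reaches nominal
  significance (≈1 cohort in 20).
- The noisy per-sweep fiber volley is a windowed minimum and is biased
  upward by ≈σ·E[max] (~0.04 mV at σ = 0.05 mV); group comparisons are
  unaffected because the bias is common to both groups.
- ATF support covers the tab-delimited text layout described in the I/O
  module only; vendor binary formats are out of scope.
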