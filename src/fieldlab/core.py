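"""Core domain types for extracellular field-potential recordings.

Canonical units throughout the package: voltage in mV, time within a sweep
in ms, stimulus current in µA, experiment time (``t_acquired``) in minutes.
All readers convert on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .errors import ValidationError

#: Default sampling interval, ms per sample (10 kHz acquisition).
DEFAULT_SAMPLE_INTERVAL_MS = 0.1

PROTOCOL_KINDS = ("baseline", "io_ramp", "paired_pulse", "tbs", "ltp_experiment")


@dataclass
class Sweep:
    """One digitized voltage trace.

    Parameters
    ----------
    sample_interval : float
        Time between samples, ms. Default 0.1 ms (10 kHz).
    samples : ndarray
        Voltages in mV, ``V_x`` for ``x = 0..N-1``.
    stimulus_times : list of float
        Stimulus onset times in ms from the start of the sweep.
    stimulus_intensity : float
        Stimulating current, µA.
    sweep_index : int
        Ordinal position within the recording.
    t_acquired : float
        Time offset of the sweep within the experiment, minutes.
    meta : dict
        Free-form annotations (e.g. ``phase`` for LTP experiments).
    """

    samples: np.ndarray
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL_MS
    stimulus_times: list[float] = field(default_factory=list)
    stimulus_intensity: float = 0.0
    sweep_index: int = 0
    t_acquired: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_interval <= 0:
            raise ValidationError("sample_interval must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("a sweep needs at least 2 samples")
        times = list(self.stimulus_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("stimulus_times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] >= self.duration):
            raise ValidationError("stimulus_times must lie within the sweep")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Sweep duration in ms."""
        return self.n_samples * self.sample_interval

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms, 0-based at the first sample."""
        return np.arange(self.n_samples) * self.sample_interval

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms (clipped to the sweep)."""
        return int(np.clip(round(t_ms / self.sample_interval), 0, self.n_samples - 1))


@dataclass
class StimulusProtocol:
    """Declarative description of a stimulation experiment.

    ``pulse_times`` are within-sweep stimulus times (ms); ``intensities``
    gives the stimulating current per sweep (a scalar is broadcast).
    ``inter_sweep_interval`` is in seconds (10 s = 0.1 Hz delivery) and
    ``pulse_width`` in µs is carried as acquisition metadata.
    """

    kind: str
    pulse_times: list[float] = field(default_factory=list)
    intensities: list[float] | None = None
    inter_sweep_interval: float = 10.0
    pulse_width: float = 200.0
    isi: float = 50.0
    n_sweeps: int | None = None
    sweep_duration: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValidationError(
                f"unknown protocol kind {self.kind!r}; expected one of {PROTOCOL_KINDS}"
            )
        if self.inter_sweep_interval <= 0:
            raise ValidationError("inter_sweep_interval must be > 0")


@dataclass
class Recording:
    """An ordered collection of sweeps sharing one time base."""

    sweeps: list[Sweep]
    protocol: StimulusProtocol | None = None
    label: str = ""
    slice_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.sweeps:
            si = self.sweeps[0].sample_interval
            if any(abs(s.sample_interval - si) > 1e-12 for s in self.sweeps):
                raise ValidationError("all sweeps must share one sample_interval")
            t = [s.t_acquired for s in self.sweeps]
            if any(b < a for a, b in zip(t, t[1:])):
                raise ValidationError("sweep t_acquired must be non-decreasing")

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    @property
    def sample_interval(self) -> float:
        if not self.sweeps:
            raise ValidationError("empty recording has no sample_interval")
        return self.sweeps[0].sample_interval


@dataclass
class GroupSummary:
    """n, mean and standard error (sd/√n) of one group's per-slice statistic."""

    n: int
    mean: float
    se: float
    units: str = ""

    @classmethod
    def from_values(cls, values: Sequence[float], units: str = "") -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValidationError("need n >= 2 to compute a standard error")
        return cls(n=int(v.size), mean=float(v.mean()),
                   se=float(v.std(ddof=1) / np.sqrt(v.size)), units=units)


@dataclass
class GroupComparison:
    """Welch two-sample comparison of per-slice statistics."""

    label_a: str
    label_b: str
    mean_a: float
    se_a: float
    n_a: int
    mean_b: float
    se_b: float
    n_b: int
    t_stat: float
    df: float
    p_two_tailed: float
    values_a: list[float] | None = None
    values_b: list[float] | None = None
    removed_a: list[int] = field(default_factory=list)
    removed_b: list[int] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05

    def stars(self) -> str:
        """Asterisk convention: * p<0.05, ** p<0.01."""
        if self.p_two_tailed < 0.01:
            return "**"
        if self.p_two_tailed < 0.05:
            return "*"
        return ""
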