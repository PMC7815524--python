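"""Analysis configuration: measurement windows, inclusion thresholds, simulation
and statistics options, loadable from YAML/JSON with a strict schema.

All defaults mirror the recording and analysis conventions the package
implements: ≤8% baseline variance for inclusion, 50 ms paired-pulse interval,
mCBI window [25, 125] ms, LTP analysis window [44, 59] min post-tetanus.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class Windows:
    """Measurement windows. Offsets are relative to stimulus onset, in ms."""

    fv_window: tuple[float, float] = (0.5, 2.5)      # fiber-volley search
    epsp_window: tuple[float, float] = (2.5, 30.0)   # fEPSP peak search
    rise_fraction: tuple[float, float] = (0.2, 0.8)  # slope-fit chord
    mcbi_window: tuple[float, float] = (25.0, 125.0)  # absolute, ms
    auc_duration: float = 100.0                      # ms from burst onset
    baseline_gap: float = 2.0                        # pre-stimulus margin, ms
    ltp_window: tuple[float, float] = (44.0, 59.0)   # min post-TBS


@dataclass
class Thresholds:
    baseline_variance_limit: float = 8.0  # percent CV of 1-min binned means
    detect_z: float = 6.0                 # artifact detection z-threshold

    def __post_init__(self) -> None:
        if self.baseline_variance_limit <= 0:
            raise ValidationError("baseline_variance_limit must be > 0")
        if self.detect_z <= 0:
            raise ValidationError("detect_z must be > 0")


@dataclass
class Simulation:
    isi: float = 50.0            # paired-pulse inter-stimulus interval, ms
    n_ppr_sweeps: int = 12
    baseline_min: float = 20.0   # pre-tetanus baseline duration, min
    followup_min: float = 60.0   # post-tetanus follow-up, min


@dataclass
class Stats:
    alpha: float = 0.05
    grubbs_alpha: float = 0.05
    grubbs_screen: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "grubbs_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValidationError(f"{name} must be in (0, 1)")


@dataclass
class AnalysisConfig:
    windows: Windows = field(default_factory=Windows)
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: Simulation = field(default_factory=Simulation)
    stats: Stats = field(default_factory=Stats)


_SECTIONS = {
    "windows": Windows,
    "thresholds": Thresholds,
    "simulation": Simulation,
    "stats": Stats,
}

_TUPLE_FIELDS = {"fv_window", "epsp_window", "rise_fraction", "mcbi_window", "ltp_window"}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
        )
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ValidationError(f"[{section}] {key} must be a [lo, hi] pair")
            lo, hi = float(value[0]), float(value[1])
            if hi <= lo:
                raise ValidationError(f"[{section}] {key}: upper bound must exceed lower")
            kwargs[key] = (lo, hi)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML (or JSON) file.

    An empty file — or ``path=None`` — yields all defaults. Unknown sections
    or keys raise :class:`~fieldlab.errors.ValidationError`.
    """
    if path is None:
        return AnalysisConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return AnalysisConfig()
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping of sections")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValidationError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            body = data[section]
            if body is None:
                body = {}
            if not isinstance(body, dict):
                raise ValidationError(f"config section [{section}] must be a mapping")
            kwargs[section] = _build_section(cls, body, section)
    return AnalysisConfig(**kwargs)
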