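"""Readers and writers for sweep-table files.

Two text dialects share one :class:`~fieldlab.core.Recording` contract:

* **csv** — header ``time_ms,sweep_0001,...``, one row per sample, voltages
  in mV. Stimulus annotations, intensities and labels travel in a JSON
  sidecar ``<name>.meta.json`` next to the data file.
* **atf** — Axon Text File: tab-delimited; line 1 ``ATF<TAB>1.0``; line 2
  ``<nHeaderRecords><TAB><nColumns>``; then the quoted header records, a
  column-title line, and data rows (time in ms, sweeps in mV). The same JSON
  sidecar carries the stimulus metadata.

Voltages are written with 8 significant digits, so a round trip is
value-identical well beyond the 6-digit contract; times and intensities are
exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Recording, StimulusProtocol, Sweep
from .errors import DataError, FormatError, ValidationError

DIALECTS = ("csv", "atf")


# ---------------------------------------------------------------------------
# sidecar metadata
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _meta_from_recording(recording: Recording) -> dict:
    meta = {
        "label": recording.label,
        "slice_id": recording.slice_id,
        "animal_id": recording.animal_id,
        "stimulus_times": [list(s.stimulus_times) for s in recording],
        "intensities": [s.stimulus_intensity for s in recording],
        "t_acquired": [s.t_acquired for s in recording],
        "sweep_meta": [s.meta for s in recording],
    }
    if recording.protocol is not None:
        p = recording.protocol
        meta["protocol"] = {
            "kind": p.kind,
            "pulse_times": list(p.pulse_times),
            "intensities": None if p.intensities is None else list(p.intensities),
            "inter_sweep_interval": p.inter_sweep_interval,
            "pulse_width": p.pulse_width,
            "isi": p.isi,
            "n_sweeps": p.n_sweeps,
            "sweep_duration": p.sweep_duration,
            "meta": p.meta,
        }
    return meta


def _apply_meta(sweeps: list[Sweep], meta: dict) -> Recording:
    n = len(sweeps)
    times = meta.get("stimulus_times") or [[]] * n
    intens = meta.get("intensities") or [0.0] * n
    t_acq = meta.get("t_acquired") or [0.0] * n
    s_meta = meta.get("sweep_meta") or [{}] * n
    for i, s in enumerate(sweeps):
        if i < len(times):
            s.stimulus_times = [float(x) for x in times[i]]
        if i < len(intens):
            s.stimulus_intensity = float(intens[i])
        if i < len(t_acq):
            s.t_acquired = float(t_acq[i])
        if i < len(s_meta):
            s.meta = dict(s_meta[i])
    protocol = None
    if "protocol" in meta:
        protocol = StimulusProtocol(**meta["protocol"])
    return Recording(sweeps=sweeps, protocol=protocol,
                     label=meta.get("label", ""),
                     slice_id=meta.get("slice_id", ""),
                     animal_id=meta.get("animal_id", ""))


# ---------------------------------------------------------------------------
# shared column plumbing
# ---------------------------------------------------------------------------

def _sweeps_from_columns(time_ms: np.ndarray, columns: np.ndarray,
                         source: str) -> list[Sweep]:
    if time_ms.size < 2:
        raise DataError(f"{source}: need at least 2 samples")
    dt = np.diff(time_ms)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2
        raise DataError(f"{source}: non-monotonic time column at data row {bad}")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise DataError(f"{source}: time column is not uniformly sampled")
    si = float(dt[0])
    return [Sweep(samples=columns[:, j], sample_interval=si, sweep_index=j)
            for j in range(columns.shape[1])]


def _format_rows(time_ms: np.ndarray, data: np.ndarray, sep: str) -> list[str]:
    rows = []
    for i in range(time_ms.size):
        cells = [f"{time_ms[i]:.8g}"] + [f"{v:.8g}" for v in data[i]]
        rows.append(sep.join(cells))
    return rows


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_sweep_table(path: str | Path, dialect: str = "csv") -> Recording:
    """Read a sweep-table file (one sweep per data column) into a Recording."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise DataError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    if dialect == "csv":
        sweeps = _read_csv(lines, str(path))
    else:
        sweeps = _read_atf(lines, str(path))
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return _apply_meta(sweeps, meta)


def write_sweep_table(recording: Recording, path: str | Path,
                      dialect: str = "csv") -> None:
    """Write a Recording as a sweep table plus its JSON metadata sidecar."""
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not recording.sweeps:
        raise ValidationError("cannot write an empty recording")
    path = Path(path)
    n = recording.sweeps[0].n_samples
    if any(s.n_samples != n for s in recording):
        raise ValidationError("all sweeps must have equal length for a sweep table")
    si = recording.sample_interval
    time_ms = np.arange(n) * si
    data = np.column_stack([s.samples for s in recording])
    titles = ["time_ms"] + [f"sweep_{j + 1:04d}" for j in range(len(recording))]
    if dialect == "csv":
        lines = [",".join(titles)] + _format_rows(time_ms, data, ",")
    else:
        records = [f'"SweepCount={len(recording)}"',
                   f'"SampleIntervalMs={si:.8g}"']
        lines = ["ATF\t1.0", f"{len(records)}\t{len(titles)}", *records,
                 "\t".join(titles), *_format_rows(time_ms, data, "\t")]
    path.write_text("\n".join(lines) + "\n")
    _sidecar_path(path).write_text(
        json.dumps(_meta_from_recording(recording), indent=1))


# ---------------------------------------------------------------------------
# dialect parsers
# ---------------------------------------------------------------------------

def _parse_data_rows(rows: list[str], sep: str, n_cols: int, source: str,
                     first_line_no: int):
    time, cols = [], []
    for off, row in enumerate(rows):
        if not row.strip():
            continue
        cells = row.split(sep)
        if len(cells) != n_cols:
            raise FormatError(
                f"{source}: line {first_line_no + off}: expected {n_cols} "
                f"columns, found {len(cells)}")
        try:
            vals = [float(c) for c in cells]
        except ValueError as exc:
            raise FormatError(
                f"{source}: line {first_line_no + off}: non-numeric value "
                f"({exc})") from exc
        time.append(vals[0])
        cols.append(vals[1:])
    return np.asarray(time), np.asarray(cols)


def _read_csv(lines: list[str], source: str) -> list[Sweep]:
    if not lines:
        raise FormatError(f"{source}: empty file")
    header = lines[0].split(",")
    if len(header) < 2 or header[0].strip() != "time_ms":
        raise FormatError(
            f"{source}: line 1: header must start with 'time_ms' and name "
            f"at least one sweep column")
    time, cols = _parse_data_rows(lines[1:], ",", len(header), source, 2)
    return _sweeps_from_columns(time, cols, source)


def _read_atf(lines: list[str], source: str) -> list[Sweep]:
    if len(lines) < 3:
        raise FormatError(f"{source}: truncated ATF file")
    magic = lines[0].split("\t")
    if magic[0].strip() != "ATF":
        raise FormatError(f"{source}: line 1: not an ATF file (missing 'ATF' magic)")
    try:
        n_records, n_cols = (int(x) for x in lines[1].split("\t"))
    except ValueError as exc:
        raise FormatError(
            f"{source}: line 2: expected '<nHeaderRecords>\\t<nColumns>'") from exc
    title_line_no = 2 + n_records
    if title_line_no >= len(lines):
        raise FormatError(f"{source}: header claims {n_records} records but "
                          f"file ends early")
    for i in range(2, title_line_no):
        if not lines[i].strip().startswith('"'):
            raise FormatError(f"{source}: line {i + 1}: header record must be quoted")
    titles = lines[title_line_no].split("\t")
    if len(titles) != n_cols:
        raise FormatError(
            f"{source}: line {title_line_no + 1}: {n_cols} column titles "
            f"expected, found {len(titles)}")
    time, cols = _parse_data_rows(lines[title_line_no + 1:], "\t", n_cols,
                                  source, title_line_no + 2)
    return _sweeps_from_columns(time, cols, source)
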