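"""One-command cohort run: simulate n slices per condition, run every
protocol analysis, apply the inclusion rule, and compare the headline
metrics between conditions.

The six headline per-slice metrics are: maximal I/O slope, maximal fiber
volley, paired-pulse ratio, LTP magnitude, tetanus depolarization AUC, and
the (control-normalized) modified Coastline Burst Index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import AnalysisConfig
from .core import GroupComparison
from .errors import AnalysisError, DegenerateStatisticsError
from .metrics import normalize_metric
from .protocols import (
    analyze_io,
    analyze_ltp,
    analyze_ppr,
    build_io_ramp,
    build_ltp_experiment,
    build_paired_pulse,
    mean_mcbi,
    tetanus_depolarization,
)
from .simulate import preset, simulate_experiment
from .stats import compare_groups

log = logging.getLogger("fieldlab")

METRICS = ("io_max_slope", "io_max_fv", "ppr", "ltp", "auc", "mcbi")

METRIC_UNITS = {
    "io_max_slope": "mV/ms",
    "io_max_fv": "mV",
    "ppr": "",
    "ltp": "% baseline",
    "auc": "mV·ms",
    "mcbi": "normalized",
}


def derive_slice_seed(seed: int, condition: str, slice_index: int) -> int:
    """Deterministic per-slice seed from (cohort seed, condition, index)."""
    digest = hashlib.sha256(f"{seed}:{condition}:{slice_index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class SliceResult:
    condition: str
    slice_index: int
    seed: int
    io_max_slope: float
    io_max_fv: float
    ppr: float
    ltp: float
    auc: float
    mcbi_raw: float
    baseline_fv: float
    variance_pct: float
    included: bool
    ltp_timecourse_t: list[float]
    ltp_timecourse_slope: list[float]
    io_intensities: list[float] = field(default_factory=list)
    io_slope_curve: list[float] = field(default_factory=list)
    io_fv_curve: list[float] = field(default_factory=list)


@dataclass
class CohortResult:
    seed: int
    n_per_group: int
    slices: list[SliceResult]
    comparisons: dict[str, GroupComparison]
    underpowered: bool = False
    excluded: dict[str, list[int]] = field(default_factory=dict)

    def values(self, condition: str, metric: str) -> list[float]:
        out = []
        for s in self.slices:
            if s.condition != condition:
                continue
            if metric == "ltp" and not s.included:
                continue
            out.append(getattr(s, "mcbi_raw" if metric == "mcbi" else metric))
        return out

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_per_group": self.n_per_group,
            "underpowered": self.underpowered,
            "excluded": self.excluded,
            "slices": [dataclasses.asdict(s) for s in self.slices],
            "comparisons": {k: dataclasses.asdict(v)
                            for k, v in self.comparisons.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CohortResult":
        return cls(
            seed=data["seed"], n_per_group=data["n_per_group"],
            slices=[SliceResult(**s) for s in data["slices"]],
            comparisons={k: GroupComparison(**v)
                         for k, v in data["comparisons"].items()},
            underpowered=data.get("underpowered", False),
            excluded=data.get("excluded", {}),
        )


def analyze_slice(condition: str, slice_index: int, slice_seed: int,
                  config: AnalysisConfig) -> SliceResult:
    """Simulate and analyze all protocols for one slice."""
    sim = config.simulation
    params = preset(condition, seed=slice_seed)

    io = analyze_io(simulate_experiment(params, build_io_ramp()), config)
    ppr = analyze_ppr(simulate_experiment(
        params, build_paired_pulse(isi=sim.isi, n_sweeps=sim.n_ppr_sweeps,
                                   stim_onset=params.stim_onset)), config)
    ltp_rec = simulate_experiment(
        params, build_ltp_experiment(baseline_min=sim.baseline_min,
                                     followup_min=sim.followup_min))
    ltp = analyze_ltp(ltp_rec, config)
    tbs_sweeps = [s for s in ltp_rec if s.meta.get("phase") == "tbs"]
    auc = tetanus_depolarization(tbs_sweeps, config)
    mcbi = mean_mcbi(tbs_sweeps, config)

    return SliceResult(
        condition=condition, slice_index=slice_index, seed=slice_seed,
        io_max_slope=io.max_slope, io_max_fv=io.max_fv,
        ppr=ppr.ppr, ltp=ltp.ltp_magnitude, auc=auc.mean_auc, mcbi_raw=mcbi,
        baseline_fv=ltp.baseline_fv, variance_pct=ltp.variance_pct,
        included=ltp.included,
        ltp_timecourse_t=[float(x) for x in ltp.timecourse_t],
        ltp_timecourse_slope=[float(x) for x in ltp.timecourse_slope],
        io_intensities=[float(x) for x in io.intensities],
        io_slope_curve=[float(x) for x in io.mean_slope],
        io_fv_curve=[float(x) for x in io.mean_fv],
    )


def run_cohort(config: AnalysisConfig | None = None, n_per_group: int = 6,
               seed: int = 0, conditions: tuple[str, str] = ("air", "hyperoxia"),
               ) -> CohortResult:
    """Simulate and analyze a full two-condition cohort.

    Each slice gets a distinct seed derived from ``(seed, condition, index)``.
    Slices failing the ≤8% baseline-variance rule are excluded from the LTP
    comparison (logged with their variance). Comparisons are marked
    underpowered — and skipped — when a group has fewer than 2 usable slices.
    """
    cfg = config or AnalysisConfig()
    label_a, label_b = conditions
    slices: list[SliceResult] = []
    for cond in conditions:
        for i in range(n_per_group):
            s = analyze_slice(cond, i, derive_slice_seed(seed, cond, i), cfg)
            if not s.included:
                log.warning("excluded %s slice %d: baseline variance %.1f%%",
                            cond, i, s.variance_pct)
            slices.append(s)

    excluded = {c: [s.slice_index for s in slices
                    if s.condition == c and not s.included]
                for c in conditions}
    for cond in conditions:
        if len(excluded[cond]) == n_per_group:
            report = "; ".join(
                f"slice {s.slice_index}: {s.variance_pct:.1f}%"
                for s in slices if s.condition == cond)
            raise AnalysisError(
                f"all {cond} slices excluded by the baseline-stability rule "
                f"({report})")

    result = CohortResult(seed=seed, n_per_group=n_per_group, slices=slices,
                          comparisons={}, excluded=excluded)

    # normalize mCBI to the control-group mean
    air_mcbi = result.values(label_a, "mcbi")
    ref = float(np.mean(air_mcbi))

    for metric in METRICS:
        va = result.values(label_a, metric)
        vb = result.values(label_b, metric)
        if metric == "mcbi":
            va = list(normalize_metric(va, ref))
            vb = list(normalize_metric(vb, ref))
        try:
            cmp = compare_groups(va, vb, label_a, label_b,
                                 alpha=cfg.stats.alpha,
                                 grubbs_screen=cfg.stats.grubbs_screen,
                                 grubbs_alpha=cfg.stats.grubbs_alpha)
            for grp, rem in ((label_a, cmp.removed_a), (label_b, cmp.removed_b)):
                for idx in rem:
                    log.info("Grubbs removed %s[%d] for metric %s", grp, idx, metric)
        except DegenerateStatisticsError:
            result.underpowered = True
            continue
        result.comparisons[metric] = cmp
    if n_per_group < 2:
        result.underpowered = True
    return result


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    version: str
    inputs: list[str]
    outputs: list[str]
    timestamp: float

    @classmethod
    def create(cls, seed: int, config: AnalysisConfig,
               inputs=(), outputs=()) -> "RunManifest":
        cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True)
        return cls(command=" ".join(sys.argv),
                   config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
                   seed=seed, version=__version__,
                   inputs=list(map(str, inputs)), outputs=list(map(str, outputs)),
                   timestamp=_time.time())

    def write(self, outdir: Path) -> None:
        (outdir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=1))


def report(bundle: CohortResult, outdir: str | Path,
           conditions: tuple[str, str] = ("air", "hyperoxia")) -> dict[str, list[str]]:
    """Write summary figures and full-precision CSV tables for a cohort run.

    Produces five figures (I/O slope, I/O fiber volley, PPR, LTP timecourse
    with analysis-window shading, AUC/mCBI bars) and six per-metric tables.
    Returns the file lists. Missing metrics are reported as absent, not fatal.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    figures: list[str] = []
    tables: list[str] = []
    colors = {conditions[0]: "tab:blue", conditions[1]: "tab:red"}

    def per_slice_frame(metric: str) -> pd.DataFrame:
        rows = []
        for s in bundle.slices:
            rows.append({"condition": s.condition, "slice": s.slice_index,
                         "value": getattr(s, "mcbi_raw" if metric == "mcbi"
                                          else metric),
                         "included": s.included})
        return pd.DataFrame(rows)

    # per-slice tables for the bar metrics, exact bundle values
    for metric in ("ppr", "auc", "mcbi"):
        f = outdir / f"{metric}.csv"
        per_slice_frame(metric).to_csv(f, index=False)
        tables.append(str(f))

    # intensity-curve tables
    for metric, attr in (("io_slope", "io_slope_curve"), ("io_fv", "io_fv_curve")):
        rows = []
        for s in bundle.slices:
            for inten, val in zip(s.io_intensities, getattr(s, attr)):
                rows.append({"condition": s.condition, "slice": s.slice_index,
                             "intensity_uA": inten, "value": val})
        f = outdir / f"{metric}.csv"
        pd.DataFrame(rows).to_csv(f, index=False)
        tables.append(str(f))

    # figure: group-mean bar chart helper
    def bar_fig(metric: str, title: str, fname: str):
        fig, ax = plt.subplots(figsize=(3.2, 3.2))
        cmp = bundle.comparisons.get(metric)
        if cmp is None:
            ax.set_title(f"{title}\n(absent)")
        else:
            ax.bar([0, 1], [cmp.mean_a, cmp.mean_b],
                   yerr=[cmp.se_a, cmp.se_b],
                   color=[colors[c] for c in conditions], capsize=4)
            ax.set_xticks([0, 1], conditions)
            ax.set_title(f"{title} {cmp.stars()}")
            ax.set_ylabel(METRIC_UNITS.get(metric, ""))
        fig.tight_layout()
        f = outdir / fname
        fig.savefig(f, dpi=120)
        plt.close(fig)
        figures.append(str(f))

    bar_fig("ppr", "Paired-pulse ratio", "ppr.png")

    # figure: AUC and mCBI bars side by side
    fig, axes = plt.subplots(1, 2, figsize=(6, 3.2))
    for ax, metric, title in zip(axes, ("auc", "mcbi"),
                                 ("Tetanus AUC", "mCBI (norm.)")):
        cmp = bundle.comparisons.get(metric)
        if cmp is None:
            ax.set_title(f"{title}\n(absent)")
            continue
        ax.bar([0, 1], [cmp.mean_a, cmp.mean_b], yerr=[cmp.se_a, cmp.se_b],
               color=[colors[c] for c in conditions], capsize=4)
        ax.set_xticks([0, 1], conditions)
        ax.set_title(f"{title} {cmp.stars()}")
        ax.set_ylabel(METRIC_UNITS[metric])
    fig.tight_layout()
    f = outdir / "auc_mcbi.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    figures.append(str(f))

    # figures: I/O curves (mean ± SE across slices per condition)
    for attr, ylab, fname in (("io_slope_curve", "fEPSP slope (mV/ms)", "io_slope.png"),
                              ("io_fv_curve", "fiber volley (mV)", "io_fv.png")):
        fig, ax = plt.subplots(figsize=(4.2, 3.4))
        for cond in conditions:
            curves = [getattr(s, attr) for s in bundle.slices
                      if s.condition == cond and s.io_intensities]
            if not curves:
                continue
            intens = next(s.io_intensities for s in bundle.slices
                          if s.condition == cond and s.io_intensities)
            mat = np.vstack(curves)
            ax.errorbar(intens, mat.mean(axis=0),
                        yerr=mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
                        if mat.shape[0] > 1 else None,
                        fmt="o-", ms=3, color=colors[cond], label=cond)
        ax.set_xlabel("stimulus intensity (µA)")
        ax.set_ylabel(ylab)
        ax.legend()
        fig.tight_layout()
        f = outdir / fname
        fig.savefig(f, dpi=120)
        plt.close(fig)
        figures.append(str(f))

    # figure: LTP timecourse with analysis-window shading
    fig, ax = plt.subplots(figsize=(5.2, 3.4))
    any_tc = False
    for cond in conditions:
        curves = [(s.ltp_timecourse_t, s.ltp_timecourse_slope)
                  for s in bundle.slices if s.condition == cond and s.included]
        if not curves:
            continue
        any_tc = True
        t = np.asarray(curves[0][0])
        mat = np.vstack([c[1] for c in curves])
        ax.errorbar(t, mat.mean(axis=0),
                    yerr=mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
                    if mat.shape[0] > 1 else None,
                    fmt="o", ms=3, color=colors[cond], label=cond)
    if any_tc:
        ax.axvspan(44, 59, color="0.9")
        ax.axhline(100, ls="--", color="0.5")
        ax.set_xlabel("time from TBS (min)")
        ax.set_ylabel("fEPSP slope (% baseline)")
        ax.legend()
        tc_rows = []
        for s in bundle.slices:
            for t, v in zip(s.ltp_timecourse_t, s.ltp_timecourse_slope):
                tc_rows.append({"condition": s.condition, "slice": s.slice_index,
                                "t_min": t, "normalized_slope_pct": v})
        f = outdir / "ltp_timecourse.csv"
        pd.DataFrame(tc_rows).to_csv(f, index=False)
        tables.append(str(f))
    else:
        log.warning("empty LTP timecourse; table omitted")
        ax.set_title("LTP timecourse (absent)")
    fig.tight_layout()
    f = outdir / "ltp_timecourse.png"
    fig.savefig(f, dpi=120)
    plt.close(fig)
    figures.append(str(f))

    return {"figures": figures, "tables": tables}
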