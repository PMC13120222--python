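"""Trace/registry/config readers and writers, plus pipeline orchestration.

All interchange is tidy CSV with unit-bearing column names; per-trace
metadata (leaf area, chamber molar content, treatment, replicate, seed)
lives in a YAML sidecar next to the trace file.  A pipeline run writes its
effective configuration next to its outputs, and every number in a report
traces back to an input file via provenance columns.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CHANNEL_PREFIX, TIME_COLUMN, ChamberGeometry, LeafTrace
from .decay_kinetics import DecayStageError, DecayWindows, analyze_decay
from .ptr_flux import (
    DEFAULT_REGISTRY,
    GROUPS,
    ChannelRegistry,
    aggregate_groups,
    trace_fluxes,
)
from .response_models import build_report
from .synth_leaf import ExperimentConfig, NoiseModel, generate_experiment

log = logging.getLogger("leafvoc")

REQUIRED_COLUMNS = (TIME_COLUMN,)
OPTIONAL_DEFAULTS = {
    "ppfd": np.nan,
    "t_leaf_c": np.nan,
    "co2_umol_mol": np.nan,
    "q_flow_umol_s": np.nan,
    "a_net": np.nan,
}


class PipelineError(RuntimeError):
    pass


def _meta_path(trace_path: Path) -> Path:
    return trace_path.with_suffix("").with_suffix(".meta.yaml") \
        if trace_path.suffix == ".csv" else trace_path.with_suffix(".meta.yaml")


def write_trace(trace: LeafTrace, directory: str | Path) -> Path:
    """Write a trace as ``<trace_id>.csv`` plus a YAML metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{trace.trace_id}.csv"
    trace.data.to_csv(path, index=False)
    geom = trace.geometry
    meta = {
        "trace_id": trace.trace_id,
        "q_flow_umol_s": geom.q_flow_umol_s,
        "a_leaf_m2": geom.a_leaf_m2,
        "n_chamber_umol": geom.n_chamber_umol,
        "chi_in": geom.chi_in if not isinstance(geom.chi_in, dict)
        else dict(geom.chi_in),
        **{k: v for k, v in trace.meta.items()},
    }
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_trace(path: str | Path) -> LeafTrace:
    """Read a tidy trace CSV (+ optional sidecar) into a :class:`LeafTrace`.

    Time must be strictly increasing (duplicated timestamps are rejected with
    the offending line); missing optional environment columns are defaulted
    with a logged notice; unknown extra columns are preserved.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if not any(c.startswith(CHANNEL_PREFIX) for c in df.columns):
        raise ValueError(f"{path}: no {CHANNEL_PREFIX}<m/z> channel columns")
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based indexing
        raise ValueError(
            f"{path}: non-increasing {TIME_COLUMN} at data line {bad[0] + 2} "
            f"(t={t[bad[0]]} followed by t={t[bad[0] + 1]})"
        )
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            log.info("%s: optional column %r absent, defaulting", path, col)
            df[col] = default

    meta_file = _meta_path(path)
    meta: dict = {}
    geom = ChamberGeometry()
    if meta_file.exists():
        meta = yaml.safe_load(meta_file.read_text()) or {}
        geom = ChamberGeometry(
            q_flow_umol_s=float(meta.get("q_flow_umol_s", 500.0)),
            a_leaf_m2=float(meta.get("a_leaf_m2", 6.0e-4)),
            n_chamber_umol=float(meta.get("n_chamber_umol", 0.0)),
            chi_in=meta.get("chi_in", 0.0),
        )
    else:
        log.info("%s: no metadata sidecar, using default chamber geometry",
                 path)
    trace_id = str(meta.get("trace_id", path.stem))
    return LeafTrace(trace_id=trace_id, data=df, geometry=geom, meta=meta)


def write_simtruth(truths, path: str | Path) -> Path:
    """Ground-truth table keyed by (t_leaf_c, co2, replicate)."""
    rows = []
    for tr in truths:
        row = {
            "trace_id": tr.trace_id,
            "t_leaf_c": tr.cell.t_leaf_c,
            "co2_umol_mol": tr.cell.co2_umol_mol,
            "replicate": tr.cell.replicate_id,
            "s0_nmol_m2": tr.kinetics.s0_nmol_m2,
            "f_supply_nmol_m2_s": tr.kinetics.f_supply_nmol_m2_s,
            "k_isps_s": tr.kinetics.k_isps_s,
            "e_dark_floor": tr.kinetics.e_dark_floor,
            "a_net_true": tr.a_net_true,
            "warnings": ";".join(tr.warnings),
        }
        for g, v in tr.group_emission.items():
            row[f"emission_{g}_true"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class PipelineConfig:
    """Fully serialisable run configuration; the resolved copy is written
    next to the outputs of every run."""

    out_dir: str = "leafvoc_run"
    seed: int = 0
    traces_dir: str | None = None    # None -> simulate the experiment
    blanks_dir: str | None = None
    registry_path: str | None = None
    # simulated design
    temps_c: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0)
    co2_levels: tuple[float, ...] = (400.0, 800.0)
    replicates: int = 6
    light_duration_s: float = 300.0
    dark_duration_s: float | None = None
    cv_mult: float = 0.03
    sd_add: float = 0.01
    n_chamber_umol: float = 0.0
    chi_ambient: float = 0.2
    # analysis
    dynamic_flux: bool = False
    ss_window_s: float = 60.0
    initial_window_s: float = 10.0
    baseline_slope_frac: float = 0.005
    baseline_min_duration_s: float = 30.0
    exclude_temps: tuple[float, ...] = (40.0,)
    drop_flagged: bool = True
    write_flux_series: bool = False
    log_level: str = "INFO"

    def windows(self) -> DecayWindows:
        return DecayWindows(
            ss_window_s=self.ss_window_s,
            initial_window_s=self.initial_window_s,
            baseline_slope_frac=self.baseline_slope_frac,
            baseline_min_duration_s=self.baseline_min_duration_s,
        )

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            temps_c=tuple(self.temps_c),
            co2_levels=tuple(self.co2_levels),
            replicates=self.replicates,
            light_duration_s=self.light_duration_s,
            dark_duration_s=self.dark_duration_s,
            noise=NoiseModel(cv_mult=self.cv_mult, sd_add=self.sd_add),
            geometry=ChamberGeometry(
                n_chamber_umol=self.n_chamber_umol, chi_in=self.chi_ambient
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["temps_c"] = list(self.temps_c)
        d["co2_levels"] = list(self.co2_levels)
        d["exclude_temps"] = list(self.exclude_temps)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("temps_c", "co2_levels", "exclude_temps"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _load_traces(directory: str | Path) -> list[LeafTrace]:
    paths = sorted(Path(directory).glob("*.csv"))
    traces = []
    for p in paths:
        if p.name.endswith(".meta.csv") or p.stem.startswith("simtruth"):
            continue
        traces.append(read_trace(p))
    return traces


def _light_window_mean(fs, t_off: float, window_s: float) -> float:
    sel = (fs.time_s >= t_off - window_s) & (fs.time_s < t_off)
    if not sel.any():
        return float("nan")
    return float(fs.flux[sel].mean())


def run_pipeline(config: PipelineConfig) -> dict:
    """End-to-end run: simulate (or load) → flux → decay → respond → report.

    Deterministic given (config, seed).  Per-trace failures are logged and
    collected; the run continues with the remaining traces.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = (ChannelRegistry.from_csv(config.registry_path)
                if config.registry_path else DEFAULT_REGISTRY)
    windows = config.windows()

    blanks_by_cell: dict[tuple[float, float], LeafTrace] = {}
    truths = []
    if config.traces_dir is None:
        exp = config.experiment_config()
        traces, truths, blanks = generate_experiment(
            exp, seed=config.seed, registry=registry
        )
        traces_out = out_dir / "traces"
        for tr in traces:
            write_trace(tr, traces_out)
        for bl in blanks:
            write_trace(bl, out_dir / "blanks")
        write_simtruth(truths, out_dir / "simtruth.csv")
        for bl in blanks:
            blanks_by_cell[(bl.meta["t_leaf_c"], bl.meta["co2_umol_mol"])] = bl
    else:
        traces = _load_traces(config.traces_dir)
        if config.blanks_dir:
            for bl in _load_traces(config.blanks_dir):
                key = (float(bl.meta.get("t_leaf_c", math.nan)),
                       float(bl.meta.get("co2_umol_mol", math.nan)))
                blanks_by_cell[key] = bl
    if not traces:
        raise PipelineError("empty input set: no traces to analyse")

    rows, failures, flux_rows = [], [], []
    for trace in traces:
        try:
            key = (float(trace.meta.get("t_leaf_c",
                                        trace.data["t_leaf_c"].iloc[0])),
                   float(trace.meta.get("co2_umol_mol",
                                        trace.data["co2_umol_mol"].iloc[0])))
            blank = blanks_by_cell.get(key)
            result = analyze_decay(trace, windows=windows, registry=registry,
                                   blank=blank, dynamic=config.dynamic_flux)
            fluxes = trace_fluxes(trace, registry=registry, blank=blank,
                                  dynamic=config.dynamic_flux)
            groups = aggregate_groups(
                {c: f for c, f in fluxes.items() if f.group is not None},
                registry=registry,
            )
            row = {
                "trace_id": trace.trace_id,
                "t_leaf_c": key[0],
                "co2_umol_mol": key[1],
                "replicate": trace.meta.get("replicate", 0),
                "a_net": float(np.nanmean(trace.data["a_net"]))
                if "a_net" in trace.data.columns else float("nan"),
                "t_off_s": result.t_off_s,
                "e_iso": result.e_ss,
                "e_dark": result.e_dark,
                "s_pool_nmol_m2": result.s_pool_nmol_m2,
                "k_loglin_s": result.k_loglin_s,
                "k_slope_s": result.k_slope_s,
                "k_ratio_s": result.k_ratio_s,
                "r2_loglin": result.r2_loglin,
                "blank_corrected": blank is not None,
                "flags": ";".join(result.flags),
            }
            for g in GROUPS:
                if g in groups:
                    row[f"flux_{g}"] = _light_window_mean(
                        groups[g], result.t_off_s, windows.ss_window_s
                    )
            rows.append(row)
            if config.write_flux_series:
                for compound, fs in fluxes.items():
                    flux_rows.append(pd.DataFrame({
                        "trace_id": trace.trace_id,
                        "time_s": fs.time_s,
                        "compound": compound,
                        "group": fs.group or "unassigned",
                        "flux_nmol_m2_s": fs.flux,
                        "blank_corrected": fs.blank_corrected,
                    }))
        except (DecayStageError, ValueError, KeyError) as err:
            log.warning("trace %s failed: %s", trace.trace_id, err)
            failures.append({"trace_id": trace.trace_id, "error": str(err)})

    if not rows:
        raise PipelineError("every trace failed; nothing to report")

    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "decay_results.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
    if flux_rows:
        pd.concat(flux_rows, ignore_index=True).to_csv(
            out_dir / "fluxes.csv", index=False
        )

    report = build_report(summary, exclude_temps=config.exclude_temps,
                          drop_flagged=config.drop_flagged)
    for name in ("fig1", "fig2", "fig3", "fig4"):
        report[name].to_csv(out_dir / f"report_{name}.csv", index=False)
    report["ttests"].to_csv(out_dir / "ttests.csv", index=False)
    report["sigmoid_params"].to_csv(out_dir / "sigmoid_params.csv", index=False)
    config.to_yaml(out_dir / "config_resolved.yaml")

    return {
        "n_traces": len(traces),
        "n_results": len(rows),
        "n_failures": len(failures),
        "summary": summary,
        "report": report,
        "truths": truths,
        "out_dir": str(out_dir),
    }
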