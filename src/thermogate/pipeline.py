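"""End-to-end pipeline: simulate (optional) -> analyze -> report.

``run_pipeline`` executes whatever stages the config enables — synthetic
cohort generation, per-trace threshold analysis, dose-response fitting,
melt-curve Tm extraction and ddG/threshold correlation — and assembles a
RunReport with per-input results, cohort summaries (mean ± SE per
construct), the config hash, a seed registry, and every warning flag. A
run is fully deterministic given (config, seed): serializing the report
twice yields byte-identical JSON. Per-input failures are captured with a
reason and the run continues.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from .config import PipelineConfig
from .dose import fit_hill
from .exceptions import ThermogateError
from .io import read_dose, read_melt, read_panel, read_traces
from .melt import estimate_tm, normalize_melt
from .ramp import analyze_trace
from .stats import correlate_ddg_threshold
from .synthetic import GatingModelParams, simulate_heat_ramp

__all__ = ["RunReport", "run_pipeline", "write_report"]


@dataclass
class RunReport:
    config_hash: str
    software_version: str
    seed_registry: dict[str, int] = field(default_factory=dict)
    trace_results: list[dict] = field(default_factory=list)
    cohort_summaries: dict[str, dict] = field(default_factory=dict)
    dose_fits: list[dict] = field(default_factory=list)
    tm_results: list[dict] = field(default_factory=list)
    correlation: Optional[dict] = None
    skipped: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        """Canonical serialization: sorted keys, fixed separators."""
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")
        body = {
            "config_hash": self.config_hash,
            "software_version": self.software_version,
            "seed_registry": self.seed_registry,
            "trace_results": self.trace_results,
            "cohort_summaries": self.cohort_summaries,
            "dose_fits": self.dose_fits,
            "tm_results": self.tm_results,
            "correlation": self.correlation,
            "skipped": self.skipped,
            "warnings": self.warnings,
        }
        return json.dumps(body, sort_keys=True, indent=1, default=_default)


def _mean_se(values: list[float]) -> dict[str, float]:
    a = np.asarray(values, dtype=float)
    out = {"n": int(a.size), "mean": float(a.mean())}
    out["se"] = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every configured stage; see the module docstring."""
    report = RunReport(config_hash=config.config_hash(),
                       software_version=__version__)

    # ------------------------------------------------------------------ traces
    traces = []
    construct_of = {}
    if config.simulate:
        counter = 0
        for con in config.simulate:
            for k in range(con.n_traces):
                seed = (config.seed + counter) % (2 ** 31)
                counter += 1
                params = GatingModelParams.from_t_half(
                    con.t_half_C, dH=con.dH, i_max=con.i_max,
                    leak_ref=con.leak_ref, q10_leak=con.q10_leak,
                    noise_sd=con.noise_sd, seed=seed)
                tid = f"{con.name}_{k:03d}"
                report.seed_registry[tid] = seed
                traces.append(simulate_heat_ramp(params, config.protocol,
                                                 trace_id=tid))
                construct_of[tid] = con.name
    if config.traces_csv:
        for tr in read_traces(config.traces_csv, config.traces_ref_json):
            traces.append(tr)
            construct_of[tr.trace_id] = tr.trace_id.rsplit("_", 1)[0]

    by_construct: dict[str, dict[str, list[float]]] = {}
    for tr in traces:
        try:
            res = analyze_trace(tr, config.detection)
        except ThermogateError as exc:
            report.skipped.append({"input": tr.trace_id, "stage": "ramp",
                                   "reason": str(exc)})
            continue
        row = {"trace_id": tr.trace_id,
               "construct": construct_of[tr.trace_id],
               "threshold_C": round(res.threshold_C, 6),
               "q10": round(res.q10, 6) if res.q10 is not None else None,
               "t_half_act_C": (round(res.t_half_act_C, 6)
                                if res.t_half_act_C is not None else None),
               "i_at_probe_norm": (round(res.i_at_probe_norm, 6)
                                   if res.i_at_probe_norm is not None else None),
               "flags": res.flags}
        report.trace_results.append(row)
        acc = by_construct.setdefault(construct_of[tr.trace_id], {
            "threshold_C": [], "q10": [], "t_half_act_C": [],
            "i_at_probe_norm": []})
        for key in acc:
            if row[key] is not None:
                acc[key].append(row[key])

    for name, acc in by_construct.items():
        report.cohort_summaries[name] = {
            key: _mean_se(vals) for key, vals in acc.items() if vals
        }

    # ------------------------------------------------------------------- dose
    if config.dose_csv:
        df = read_dose(config.dose_csv)
        for (construct, kind), grp in df.groupby(
                ["construct", "stimulus_kind"], sort=False):
            try:
                fit = fit_hill(grp, n_bounds=config.hill_n_bounds)
            except ThermogateError as exc:
                report.skipped.append({"input": f"{construct}/{kind}",
                                       "stage": "dose", "reason": str(exc)})
                continue
            report.dose_fits.append({
                "construct": construct, "stimulus_kind": kind,
                "ec50": fit.ec50, "hill_n": fit.hill_n, "r_max": fit.r_max,
                "ph50": fit.ph50, "rss": fit.rss, "converged": fit.converged,
            })

    # ------------------------------------------------------------------- melt
    if config.melt_csv:
        for curve in read_melt(config.melt_csv):
            try:
                tm = estimate_tm(normalize_melt(curve), method=config.tm_method)
            except ThermogateError as exc:
                report.skipped.append({"input": curve.sample_id,
                                       "stage": "melt", "reason": str(exc)})
                continue
            report.tm_results.append({"sample_id": curve.sample_id,
                                      "tm_C": round(tm.tm_C, 6),
                                      "method": tm.method, "flags": tm.flags})

    # ------------------------------------------------------------------ panel
    if config.panel_tsv:
        panel = read_panel(config.panel_tsv)
        try:
            corr = correlate_ddg_threshold(panel)
            report.correlation = {"r": round(corr.r, 6), "p": corr.p,
                                  "n": corr.n,
                                  "ci95": [round(c, 6) for c in corr.ci95],
                                  "flags": corr.flags}
        except ThermogateError as exc:
            report.skipped.append({"input": config.panel_tsv, "stage": "panel",
                                   "reason": str(exc)})

    return report


def write_report(report: RunReport, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "run_report.json"
    path.write_text(report.to_json())
    if report.trace_results:
        import pandas as pd
        pd.DataFrame(report.trace_results).assign(
            flags=lambda d: d["flags"].map(";".join)
        ).to_csv(out / "trace_results.tsv", sep="\t", index=False)
    return path
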