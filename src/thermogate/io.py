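"""Tidy-CSV readers and writers; all file I/O is concentrated here.

Schemas
-------
traces CSV      : trace_id, time_s, temp_C, current_nA (long format, one row
                  per sample); capsaicin reference currents in a sidecar
                  JSON mapping trace_id -> magnitude in nA.
dose CSV        : construct, stimulus_kind, dose, replicate, response.
melt plate CSV  : sample_id, temp_C, fluorescence.
mutant panel TSV: mutant_id, position, ddG_kcal_mol, threshold_C.

Analysis operations never touch files; they take and return in-memory
objects, which keeps them unit-testable.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DomainError, ParseError
from .synthetic import MeltCurve, TemperatureTrace

__all__ = [
    "read_traces", "write_traces", "read_dose", "write_dose",
    "read_melt", "write_melt", "read_panel", "write_panel",
]

TRACE_COLUMNS = ["trace_id", "time_s", "temp_C", "current_nA"]
DOSE_COLUMNS = ["construct", "stimulus_kind", "dose", "replicate", "response"]
MELT_COLUMNS = ["sample_id", "temp_C", "fluorescence"]
PANEL_COLUMNS = ["mutant_id", "position", "ddG_kcal_mol", "threshold_C"]


def _read_table(path, columns, sep=","):
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path} header missing required column",
                         line=1, column=missing[0])
    return df


def read_traces(path, ref_json: Optional[str] = None) -> list[TemperatureTrace]:
    """Read heat-ramp traces from a tidy CSV (+ optional reference sidecar)."""
    df = _read_table(path, TRACE_COLUMNS)
    refs = {}
    if ref_json is not None:
        with open(ref_json) as fh:
            refs = json.load(fh)
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        first_line = int(grp.index[0]) + 2  # header + 1-based
        try:
            traces.append(TemperatureTrace(
                trace_id=str(tid),
                time_s=grp["time_s"].to_numpy(dtype=float),
                temp_C=grp["temp_C"].to_numpy(dtype=float),
                current_nA=grp["current_nA"].to_numpy(dtype=float),
                i_capsaicin_nA=refs.get(str(tid)),
            ))
        except DomainError as exc:
            raise ParseError(f"trace {tid!r}: {exc}", line=first_line) from exc
    if not traces:
        raise ParseError(f"{path} contains no traces")
    return traces


def write_traces(traces: list[TemperatureTrace], path,
                 ref_json: Optional[str] = None) -> None:
    frames = [pd.DataFrame({"trace_id": tr.trace_id, "time_s": tr.time_s,
                            "temp_C": tr.temp_C, "current_nA": tr.current_nA})
              for tr in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if ref_json is not None:
        refs = {tr.trace_id: tr.i_capsaicin_nA for tr in traces
                if tr.i_capsaicin_nA is not None}
        with open(ref_json, "w") as fh:
            json.dump(refs, fh, indent=1, sort_keys=True)


def read_dose(path) -> pd.DataFrame:
    df = _read_table(path, DOSE_COLUMNS)
    for i, dose in enumerate(df["dose"]):
        kind = df["stimulus_kind"].iloc[i]
        if kind == "capsaicin" and not dose > 0:
            raise ParseError("capsaicin dose must be positive",
                             line=i + 2, column="dose")
        if kind == "acid" and not (0 < dose < 14):
            raise ParseError("pH must lie in (0, 14)",
                             line=i + 2, column="dose")
    return df


def write_dose(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_melt(path) -> list[MeltCurve]:
    df = _read_table(path, MELT_COLUMNS)
    curves = []
    for sid, grp in df.groupby("sample_id", sort=False):
        first_line = int(grp.index[0]) + 2
        try:
            curves.append(MeltCurve(
                sample_id=str(sid),
                temp_C=grp["temp_C"].to_numpy(dtype=float),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            ))
        except DomainError as exc:
            raise ParseError(f"melt curve {sid!r}: {exc}",
                             line=first_line) from exc
    if not curves:
        raise ParseError(f"{path} contains no melt curves")
    return curves


def write_melt(curves: list[MeltCurve], path) -> None:
    frames = [pd.DataFrame({"sample_id": c.sample_id, "temp_C": c.temp_C,
                            "fluorescence": c.fluorescence}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = _read_table(path, PANEL_COLUMNS, sep="\t")
    if df["mutant_id"].duplicated().any():
        dup = df["mutant_id"][df["mutant_id"].duplicated()].iloc[0]
        raise ParseError(f"duplicate mutant_id {dup!r}", column="mutant_id")
    return df


def write_panel(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
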