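"""Readers and writers for the package's delimited-text tables.

All tables are comma-separated with a header row and decimal-point numerics
(locale-independent).  Schemas:

* lane table: ``construct,replicate,time_min,cy5_dna,cy5_ig4,cy5_hg4,
  sybr_rna,sybr_dna,sybr_ig4,sybr_hg4``
* quantified table: ``construct,replicate,time_min,dna_frac,ig4_frac,
  hg4_frac,rna_norm,hg4_ig4_ratio``
* time-course table: ``time_min,dna_frac,ig4_frac,hg4_frac[,rna_level]``
* trace table (long format): ``molecule_id,frame,excitation,donor,acceptor``
* summary table: one row per construct with the correlation-ledger columns

Malformed rows are rejected with their (1-based, header-inclusive) line
number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import TableFormatError
from .gel import GelLane
from .kinetics import SpeciesTimeCourse
from .smfret import FretTrace

__all__ = [
    "read_lane_table",
    "write_lane_table",
    "read_quantified_table",
    "write_quantified_table",
    "read_timecourse",
    "write_timecourse",
    "read_traces",
    "write_traces",
    "read_summary_table",
    "write_summary_table",
]

LANE_COLUMNS = [
    "construct", "replicate", "time_min",
    "cy5_dna", "cy5_ig4", "cy5_hg4",
    "sybr_rna", "sybr_dna", "sybr_ig4", "sybr_hg4",
]
QUANT_COLUMNS = [
    "construct", "replicate", "time_min",
    "dna_frac", "ig4_frac", "hg4_frac", "rna_norm", "hg4_ig4_ratio",
]
TIMECOURSE_COLUMNS = ["time_min", "dna_frac", "ig4_frac", "hg4_frac"]
TRACE_COLUMNS = ["molecule_id", "frame", "excitation", "donor", "acceptor"]


def _read_csv(path, required, numeric, nonnegative=()):
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TableFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing column(s) {missing}; header must contain {required}"
        )
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise TableFormatError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"'{col}' at line {row}"
            )
        df[col] = coerced
    for col in nonnegative:
        neg = df[col] < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0]) + 2
            raise TableFormatError(
                f"{path}: negative value in column '{col}' at line {row}"
            )
    return df


def read_lane_table(path) -> pd.DataFrame:
    """Read a raw gel-lane intensity table."""
    numeric = LANE_COLUMNS[2:]
    df = _read_csv(path, LANE_COLUMNS, numeric, nonnegative=numeric)
    df["construct"] = df["construct"].fillna("").astype(str)
    return df


def write_lane_table(lanes, path) -> None:
    """Write GelLane records (or a conforming DataFrame) as CSV."""
    if isinstance(lanes, pd.DataFrame):
        df = lanes[LANE_COLUMNS]
    else:
        df = pd.DataFrame(
            [
                {
                    "construct": l.construct_code,
                    "replicate": l.replicate_id,
                    "time_min": l.time_min,
                    "cy5_dna": l.cy5_dna,
                    "cy5_ig4": l.cy5_ig4,
                    "cy5_hg4": l.cy5_hg4,
                    "sybr_rna": l.sybr_rna,
                    "sybr_dna": l.sybr_dna,
                    "sybr_ig4": l.sybr_ig4,
                    "sybr_hg4": l.sybr_hg4,
                }
                for l in lanes
            ]
        )
    df.to_csv(path, index=False)


def read_quantified_table(path) -> pd.DataFrame:
    numeric = ["replicate", "time_min", "dna_frac", "ig4_frac", "hg4_frac", "rna_norm"]
    df = _read_csv(path, QUANT_COLUMNS, numeric + ["hg4_ig4_ratio"],
                   nonnegative=numeric[1:])
    df["construct"] = df["construct"].fillna("").astype(str)
    return df


def write_quantified_table(df: pd.DataFrame, path) -> None:
    df[QUANT_COLUMNS].to_csv(path, index=False)


def read_timecourse(path, construct_code: Optional[str] = None) -> SpeciesTimeCourse:
    """Read a normalized species time course (optionally with rna_level)."""
    df = _read_csv(
        path, TIMECOURSE_COLUMNS,
        TIMECOURSE_COLUMNS + (["rna_level"] if "rna_level" in pd.read_csv(path, nrows=0).columns else []),
        nonnegative=TIMECOURSE_COLUMNS,
    )
    return SpeciesTimeCourse.from_frame(df, construct_code=construct_code)


def write_timecourse(tc: SpeciesTimeCourse, path) -> None:
    tc.to_frame().to_csv(path, index=False)


def read_traces(path, frame_interval: float = 0.1) -> list:
    """Read a long-format trace table into FretTrace objects."""
    df = _read_csv(path, TRACE_COLUMNS, ["frame", "donor", "acceptor"],
                   nonnegative=["donor", "acceptor"])
    bad = ~df["excitation"].isin(["green", "red", "dark"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise TableFormatError(
            f"{path}: excitation must be green/red/dark (line {row})"
        )
    traces = []
    for mol, g in df.groupby("molecule_id", sort=False):
        g = g.sort_values("frame")
        traces.append(
            FretTrace(
                donor=g["donor"].to_numpy(),
                acceptor=g["acceptor"].to_numpy(),
                excitation=g["excitation"].to_numpy(dtype=object),
                frame_interval=frame_interval,
                molecule_id=str(mol),
            )
        )
    return traces


def write_traces(traces, path) -> None:
    rows = []
    for tr in traces:
        for f in range(len(tr)):
            rows.append(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": f,
                    "excitation": tr.excitation[f],
                    "donor": tr.donor[f],
                    "acceptor": tr.acceptor[f],
                }
            )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


SUMMARY_REQUIRED = [
    "construct_code", "rna_production", "ig4_level", "hg4_level",
    "hg4_ig4_ratio", "loop_length_mean", "loop_variance", "k1", "k2", "keq",
]


def read_summary_table(path) -> pd.DataFrame:
    numeric = [c for c in SUMMARY_REQUIRED if c != "construct_code"]
    df = _read_csv(path, SUMMARY_REQUIRED, numeric)
    return df


def write_summary_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
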