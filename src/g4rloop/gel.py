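"""Gel-lane quantification arithmetic for EMSA time courses.

Species fractions come from the Cy5 channel (which marks the dye-labelled
DNA construct): each band is divided by the total Cy5 signal of its lane.
RNA comes from the SYBR Green II channel: the summed RNA band intensity is
divided by the combined SYBR signal of the DNA, IG4 and HG4 bands of the
same lane.  The transcription rate is the OLS slope of normalized RNA
versus time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, NormalizationError
from .kinetics import SpeciesTimeCourse

__all__ = [
    "GelLane",
    "QuantifiedLane",
    "quantify_lane",
    "quantify_table",
    "transcription_rate",
    "TranscriptionRate",
    "hg4_ig4_ratio",
    "aggregate_replicates",
    "replicate_timecourses",
    "mean_timecourse",
    "ttest_between",
]


@dataclass(frozen=True)
class GelLane:
    """Raw band intensities of one gel lane (arbitrary units).

    Cy5-channel bands quantify the DNA species; SYBR-channel bands quantify
    total nucleic acid, with ``sybr_rna`` the *summed* intensity of all RNA
    bands in the lane (smeared RNA bands are added upstream).
    """

    time_min: float
    cy5_dna: float
    cy5_ig4: float
    cy5_hg4: float
    sybr_rna: float = 0.0
    sybr_dna: float = 0.0
    sybr_ig4: float = 0.0
    sybr_hg4: float = 0.0
    construct_code: str = ""
    replicate_id: int = 0

    def __post_init__(self):
        for name in (
            "cy5_dna", "cy5_ig4", "cy5_hg4",
            "sybr_rna", "sybr_dna", "sybr_ig4", "sybr_hg4",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.time_min < 0:
            raise ValueError(f"time_min must be >= 0, got {self.time_min}")


@dataclass(frozen=True)
class QuantifiedLane:
    """Normalized species fractions and RNA level of one lane.

    ``hg4_ig4_ratio`` is NaN when the IG4 fraction is zero (undefined,
    propagated as missing rather than infinity).
    """

    time_min: float
    dna_frac: float
    ig4_frac: float
    hg4_frac: float
    rna_norm: float
    hg4_ig4_ratio: float
    construct_code: str = ""
    replicate_id: int = 0


def hg4_ig4_ratio(hg4_frac: float, ig4_frac: float) -> float:
    """HG4/IG4 fraction ratio; NaN (with a warning) when IG4 is zero."""
    if ig4_frac == 0:
        warnings.warn(
            "IG4 fraction is zero: HG4/IG4 ratio undefined, reported as NaN",
            RuntimeWarning,
        )
        return math.nan
    return hg4_frac / ig4_frac


def quantify_lane(lane: GelLane, want_rna: bool = True) -> QuantifiedLane:
    """Normalize one lane: Cy5 fractions and SYBR-normalized RNA.

    Fractions are each Cy5 band over the lane's total Cy5 signal, so they
    sum to 1 by construction.  ``rna_norm`` is sybr_rna over the summed SYBR
    signal of the DNA/IG4/HG4 bands; it is 0 when no RNA was quantified and
    a :class:`NormalizationError` when RNA is present but the SYBR
    denominator is zero.
    """
    cy5_total = lane.cy5_dna + lane.cy5_ig4 + lane.cy5_hg4
    if cy5_total <= 0:
        raise NormalizationError(
            f"lane at t={lane.time_min} min has zero total Cy5 signal"
        )
    dna = lane.cy5_dna / cy5_total
    ig4 = lane.cy5_ig4 / cy5_total
    hg4 = lane.cy5_hg4 / cy5_total
    sybr_total = lane.sybr_dna + lane.sybr_ig4 + lane.sybr_hg4
    if want_rna and lane.sybr_rna > 0 and sybr_total <= 0:
        raise NormalizationError(
            f"lane at t={lane.time_min} min has RNA signal but zero SYBR "
            "DNA+IG4+HG4 denominator"
        )
    rna_norm = lane.sybr_rna / sybr_total if (want_rna and sybr_total > 0) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ratio = hg4_ig4_ratio(hg4, ig4)
    return QuantifiedLane(
        time_min=lane.time_min,
        dna_frac=dna,
        ig4_frac=ig4,
        hg4_frac=hg4,
        rna_norm=rna_norm,
        hg4_ig4_ratio=ratio,
        construct_code=lane.construct_code,
        replicate_id=lane.replicate_id,
    )


_LANE_COLUMNS = [
    "construct", "replicate", "time_min",
    "cy5_dna", "cy5_ig4", "cy5_hg4",
    "sybr_rna", "sybr_dna", "sybr_ig4", "sybr_hg4",
]


def quantify_table(df: pd.DataFrame) -> pd.DataFrame:
    """Quantify every lane of a raw lane table (see :data:`_LANE_COLUMNS`)."""
    rows = []
    for _, row in df.iterrows():
        lane = GelLane(
            time_min=float(row["time_min"]),
            cy5_dna=float(row["cy5_dna"]),
            cy5_ig4=float(row["cy5_ig4"]),
            cy5_hg4=float(row["cy5_hg4"]),
            sybr_rna=float(row.get("sybr_rna", 0.0)),
            sybr_dna=float(row.get("sybr_dna", 0.0)),
            sybr_ig4=float(row.get("sybr_ig4", 0.0)),
            sybr_hg4=float(row.get("sybr_hg4", 0.0)),
            construct_code=str(row.get("construct", "")),
            replicate_id=int(row.get("replicate", 0)),
        )
        q = quantify_lane(lane)
        rows.append(
            {
                "construct": q.construct_code,
                "replicate": q.replicate_id,
                "time_min": q.time_min,
                "dna_frac": q.dna_frac,
                "ig4_frac": q.ig4_frac,
                "hg4_frac": q.hg4_frac,
                "rna_norm": q.rna_norm,
                "hg4_ig4_ratio": q.hg4_ig4_ratio,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TranscriptionRate:
    """OLS regression of normalized RNA on time: the slope is the rate."""

    slope: float          # rna_norm per minute
    intercept: float
    r_value: float
    p_value: float
    stderr: float
    n: int


def transcription_rate(lanes: Iterable[QuantifiedLane] | pd.DataFrame) -> TranscriptionRate:
    """Transcription rate as the OLS slope of rna_norm versus time_min."""
    if isinstance(lanes, pd.DataFrame):
        t = lanes["time_min"].to_numpy(dtype=float)
        y = lanes["rna_norm"].to_numpy(dtype=float)
    else:
        lanes = list(lanes)
        t = np.array([l.time_min for l in lanes], dtype=float)
        y = np.array([l.rna_norm for l in lanes], dtype=float)
    if len(t) < 3:
        raise InsufficientDataError(
            f"transcription rate needs >= 3 time points, got {len(t)}"
        )
    if np.ptp(t) == 0:
        raise InsufficientDataError("all time points identical: degenerate design")
    res = stats.linregress(t, y)
    return TranscriptionRate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(t),
    )


def aggregate_replicates(df: pd.DataFrame, by=("construct", "time_min")) -> pd.DataFrame:
    """Per-group mean and sample SD of quantified values across replicates.

    SD uses the n-1 denominator (error bars over independent replicates) and
    is NaN for single-replicate groups.
    """
    value_cols = [
        c for c in ("dna_frac", "ig4_frac", "hg4_frac", "rna_norm", "hg4_ig4_ratio")
        if c in df.columns
    ]
    g = df.groupby(list(by))[value_cols]
    mean = g.mean()
    sd = g.std(ddof=1)
    n = g.size().rename("n_replicates")
    out = mean.join(sd, lsuffix="_mean", rsuffix="_sd").join(n)
    return out.reset_index()


def replicate_timecourses(df: pd.DataFrame, construct: Optional[str] = None) -> list:
    """Per-replicate :class:`SpeciesTimeCourse` objects from a quantified table.

    Suitable for a joint :class:`~g4rloop.kinetics.KineticModel` fit across
    replicates.
    """
    if construct is not None:
        df = df[df["construct"] == construct]
    out = []
    for rep, g in df.groupby("replicate"):
        g = g.sort_values("time_min")
        out.append(
            SpeciesTimeCourse(
                times=g["time_min"].to_numpy(),
                dna_frac=g["dna_frac"].to_numpy(),
                ig4_frac=g["ig4_frac"].to_numpy(),
                hg4_frac=g["hg4_frac"].to_numpy(),
                rna_level=g["rna_norm"].to_numpy() if "rna_norm" in g.columns else None,
                construct_code=str(construct) if construct is not None else None,
            )
        )
    return out


def mean_timecourse(df: pd.DataFrame, construct: Optional[str] = None) -> SpeciesTimeCourse:
    """Replicate-averaged time course with fractions renormalized to sum to 1."""
    if construct is not None:
        df = df[df["construct"] == construct]
    mean = df.groupby("time_min", as_index=False)[
        ["dna_frac", "ig4_frac", "hg4_frac"]
        + (["rna_norm"] if "rna_norm" in df.columns else [])
    ].mean()
    total = mean[["dna_frac", "ig4_frac", "hg4_frac"]].sum(axis=1)
    for col in ("dna_frac", "ig4_frac", "hg4_frac"):
        mean[col] = mean[col] / total
    return SpeciesTimeCourse(
        times=mean["time_min"].to_numpy(),
        dna_frac=mean["dna_frac"].to_numpy(),
        ig4_frac=mean["ig4_frac"].to_numpy(),
        hg4_frac=mean["hg4_frac"].to_numpy(),
        rna_level=mean["rna_norm"].to_numpy() if "rna_norm" in mean.columns else None,
        construct_code=str(construct) if construct is not None else None,
    )


def ttest_between(
    a: Sequence[float], b: Sequence[float], welch: bool = True
) -> tuple[float, float]:
    """Two-tailed two-sample t-test between replicate groups.

    Welch's unequal-variance form by default; ``welch=False`` uses the
    pooled-variance test.  Returns (t statistic, p value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("t-test needs >= 2 replicates per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
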