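"""Correlation ledger across PQS constructs.

Per construct, the summary row carries RNA production, the IG4 and HG4
levels at the summary time point, the HG4/IG4 ratio, loop-length features,
and the fitted rate constants.  The ledger is the matrix of pairwise
Pearson correlations among these variables (pairwise-complete over missing
values) together with the ranking of correlates of RNA production.  The
RNase-H-resistance proxy relations quantify how IG4 stability tracks the
equilibrium constant and loop length.

The ledger is descriptive — no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError

__all__ = [
    "ConstructSummary",
    "CorrelationLedger",
    "pearson",
    "spearman",
    "correlation_ledger",
    "stability_proxy_relations",
    "LEDGER_VARIABLES",
]

#: Variables entering the correlation matrix, in reporting order.
LEDGER_VARIABLES = (
    "rna_production",
    "ig4_level",
    "hg4_level",
    "hg4_ig4_ratio",
    "loop_length_mean",
    "loop_variance",
    "k1",
    "k2",
    "keq",
)


@dataclass(frozen=True)
class ConstructSummary:
    """One construct's summary statistics for the correlation ledger."""

    construct_code: str
    rna_production: float
    ig4_level: float
    hg4_level: float
    hg4_ig4_ratio: float          # NaN when IG4 level is zero
    loop_length_mean: float
    loop_variance: float
    k1: float
    k1r: float
    k2: float
    keq: float
    ig4_after_rnaseh: Optional[float] = None

    def as_row(self) -> dict:
        d = {
            "construct_code": self.construct_code,
            "rna_production": self.rna_production,
            "ig4_level": self.ig4_level,
            "hg4_level": self.hg4_level,
            "hg4_ig4_ratio": self.hg4_ig4_ratio,
            "loop_length_mean": self.loop_length_mean,
            "loop_variance": self.loop_variance,
            "k1": self.k1,
            "k1r": self.k1r,
            "k2": self.k2,
            "keq": self.keq,
        }
        if self.ig4_after_rnaseh is not None:
            d["ig4_after_rnaseh"] = self.ig4_after_rnaseh
        return d


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation over pairwise-complete values.

    NaN (with a warning) when fewer than 3 complete pairs remain or either
    variable has zero variance.
    """
    x, y = _clean_pairs(x, y)
    if len(x) < 3:
        warnings.warn(
            f"Pearson r undefined: only {len(x)} complete pairs", RuntimeWarning
        )
        return math.nan
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("Pearson r undefined: zero variance", RuntimeWarning)
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation, same missing-value conventions as pearson."""
    x, y = _clean_pairs(x, y)
    if len(x) < 3:
        warnings.warn(
            f"Spearman r undefined: only {len(x)} complete pairs", RuntimeWarning
        )
        return math.nan
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("Spearman r undefined: zero variance", RuntimeWarning)
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class CorrelationLedger:
    """Pairwise correlation matrix plus ranking of RNA-production correlates."""

    variables: tuple
    matrix: pd.DataFrame          # symmetric, unit diagonal, NaN where undefined
    n_pairs: pd.DataFrame         # complete pairs per cell
    ranking: list                 # [(variable, r)] sorted by signed r, descending
    method: str = "pearson"

    @property
    def top_positive(self) -> str:
        return self.ranking[0][0]

    @property
    def strongest_negative(self) -> str:
        return self.ranking[-1][0]

    def r(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])

    def summary(self) -> str:
        lines = [f"Correlation ledger ({self.method}, pairwise-complete)"]
        lines.append(self.matrix.round(3).to_string())
        lines.append("")
        lines.append("Correlates of rna_production (signed r, descending):")
        for name, r in self.ranking:
            lines.append(f"  {name:>18}  r = {r:+.3f}")
        return "\n".join(lines)


def correlation_ledger(
    summaries: Sequence[ConstructSummary] | pd.DataFrame,
    variables: Sequence[str] = LEDGER_VARIABLES,
    method: str = "pearson",
) -> CorrelationLedger:
    """Correlation matrix over construct summaries.

    Missing values (e.g. undefined HG4/IG4 ratios) are excluded pairwise.
    The ranking lists all non-RNA variables by their signed correlation with
    RNA production, strongest positive first.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([s.as_row() for s in summaries])
    if len(df) < 4:
        raise InsufficientDataError(
            f"correlation ledger needs >= 4 constructs, got {len(df)}"
        )
    variables = [v for v in variables if v in df.columns]
    corr_fn = {"pearson": pearson, "spearman": spearman}[method]
    k = len(variables)
    mat = np.full((k, k), np.nan)
    npairs = np.zeros((k, k), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i, a in enumerate(variables):
            for j, b in enumerate(variables):
                if j < i:
                    continue
                xa, xb = _clean_pairs(df[a], df[b])
                npairs[i, j] = npairs[j, i] = len(xa)
                if i == j:
                    mat[i, j] = 1.0
                else:
                    r = corr_fn(df[a], df[b])
                    mat[i, j] = mat[j, i] = r
    matrix = pd.DataFrame(mat, index=variables, columns=variables)
    n_pairs = pd.DataFrame(npairs, index=variables, columns=variables)
    rna_r = matrix.loc["rna_production"].drop("rna_production")
    ranking = sorted(
        [(name, float(r)) for name, r in rna_r.items() if np.isfinite(r)],
        key=lambda t: t[1],
        reverse=True,
    )
    return CorrelationLedger(
        variables=tuple(variables),
        matrix=matrix,
        n_pairs=n_pairs,
        ranking=ranking,
        method=method,
    )


def stability_proxy_relations(
    summaries: Sequence[ConstructSummary] | pd.DataFrame, method: str = "pearson"
) -> dict:
    """IG4-stability proxy correlations from RNase H resistance.

    Returns a dict with

    - ``r_resistance_vs_keq``: r(IG4 remaining after RNase H, k1/k1r) — IG4
      R-loops that survive digestion should have higher equilibrium
      constants;
    - ``r_resistance_ratio_vs_loop_length``: r(remaining/total IG4, mean
      loop length) — relative resistance should fall with loop length;

    each with the number of complete pairs.  Constructs missing the RNase-H
    field are skipped (reported in ``n``).
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([s.as_row() for s in summaries])
    if "ig4_after_rnaseh" not in df.columns:
        raise InsufficientDataError("no ig4_after_rnaseh values present")
    corr_fn = {"pearson": pearson, "spearman": spearman}[method]
    res = df["ig4_after_rnaseh"].to_numpy(dtype=float)
    keq = df["keq"].to_numpy(dtype=float)
    total = df["ig4_level"].to_numpy(dtype=float)
    loop = df["loop_length_mean"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, res / total, np.nan)
    x1, y1 = _clean_pairs(res, keq)
    if len(x1) < 4:
        raise InsufficientDataError(
            f"stability proxy needs >= 4 constructs with RNase-H data, got {len(x1)}"
        )
    r1 = corr_fn(res, keq)
    r2 = corr_fn(ratio, loop)
    x2, _ = _clean_pairs(ratio, loop)
    return {
        "r_resistance_vs_keq": r1,
        "n_resistance_vs_keq": len(x1),
        "r_resistance_ratio_vs_loop_length": r2,
        "n_resistance_ratio_vs_loop_length": len(x2),
        "method": method,
    }
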