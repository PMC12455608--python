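"""Single-molecule FRET trace analysis.

FRET efficiency is computed framewise as E = I_A / (I_D + I_A).  Molecules
are imaged under alternating laser excitation (blocks of green frames for
FRET, red frames for direct acceptor excitation, separated by dark frames),
which lets donor-only molecules be identified by their missing response to
red excitation and excluded before histogramming.  Donor spectral leakage
into the acceptor channel is estimated from the apparent efficiency of the
donor-only population (l = E_d / (1 - E_d)) and subtracted.  Histograms are
density-normalized and fitted with a least-squares sum of Gaussians; state
assignment thresholds the per-frame efficiency into low / mid / high FRET,
which in this system report duplex DNA, the HG4 R-loop (plus transient bare
R-loop), and the compact IG4 R-loop respectively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace  # noqa: F401
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import medfilt

from .exceptions import InsufficientDataError, ParameterError

__all__ = [
    "FretTrace",
    "FretHistogram",
    "StateSegmentation",
    "ExclusionResult",
    "MixtureFitResults",
    "fret_efficiency",
    "leakage_coefficient",
    "estimate_leakage",
    "correct_donor_leakage",
    "exclude_donor_only",
    "build_histogram",
    "fit_gaussian_mixture",
    "assign_states",
    "state_occupancy",
]

GREEN, RED, DARK = "green", "red", "dark"


@dataclass
class FretTrace:
    """Per-frame donor/acceptor intensities of one molecule.

    ``excitation`` labels each frame 'green' (FRET excitation), 'red'
    (direct acceptor excitation) or 'dark'.  A trace without labels is
    treated as all-green.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    excitation: Optional[np.ndarray] = None
    frame_interval: float = 0.1  # seconds; 100 ms camera frames
    molecule_id: str = ""

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.excitation is None:
            self.excitation = np.full(len(self.donor), GREEN, dtype=object)
        else:
            self.excitation = np.asarray(self.excitation, dtype=object)
        if not (len(self.donor) == len(self.acceptor) == len(self.excitation)):
            raise ValueError("donor, acceptor and excitation must have equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.donor)

    def green_mask(self) -> np.ndarray:
        return self.excitation == GREEN

    def efficiencies(self, excitation: str = GREEN) -> np.ndarray:
        """Framewise E for frames under the given excitation (NaN where both
        channels are zero)."""
        m = self.excitation == excitation
        return fret_efficiency(self.donor[m], self.acceptor[m])


def fret_efficiency(donor, acceptor):
    """E = I_A / (I_D + I_A); NaN where both intensities are zero.

    Scalar in, scalar out; arrays are handled elementwise.
    """
    d = np.asarray(donor, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    if np.any(d < 0) or np.any(a < 0):
        raise ValueError("intensities must be nonnegative")
    total = d + a
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, a / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(donor) and np.isscalar(acceptor):
        return float(e)
    return e


def leakage_coefficient(donor_only_e: float) -> float:
    """Convert a donor-only apparent efficiency into a leakage coefficient.

    A donor-only molecule with true E = 0 shows apparent E_d = l/(1+l) from
    leakage l of donor emission into the acceptor channel, so
    l = E_d / (1 - E_d).
    """
    if not 0 <= donor_only_e < 1:
        raise ParameterError(f"donor-only E must be in [0, 1), got {donor_only_e}")
    return donor_only_e / (1.0 - donor_only_e)


def estimate_leakage(donor_only_traces: Iterable[FretTrace]) -> float:
    """Leakage coefficient from the median apparent E of donor-only molecules."""
    es = []
    for tr in donor_only_traces:
        e = tr.efficiencies(GREEN)
        es.append(e[np.isfinite(e)])
    if not es or sum(len(e) for e in es) == 0:
        raise InsufficientDataError("no donor-only frames to estimate leakage from")
    e_d = float(np.median(np.concatenate(es)))
    return leakage_coefficient(e_d)


def correct_donor_leakage(trace: FretTrace, leakage: float) -> FretTrace:
    """Subtract donor leakage from the acceptor channel.

    acceptor' = max(0, acceptor - l * donor); the donor channel is
    unchanged and l = 0 is the identity.
    """
    if not 0 <= leakage < 1:
        raise ParameterError(f"leakage coefficient must be in [0, 1), got {leakage}")
    corrected = np.clip(trace.acceptor - leakage * trace.donor, 0.0, None)
    return replace(trace, acceptor=corrected)


@dataclass
class ExclusionResult:
    """Outcome of donor-only screening over a molecule cohort."""

    kept: list
    excluded: list
    flagged: list          # retained but unclassifiable (no red frames)
    threshold: float

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def excluded_fraction(self) -> float:
        n = len(self.kept) + len(self.excluded)
        return len(self.excluded) / n if n else math.nan


def exclude_donor_only(
    traces: Sequence[FretTrace],
    threshold: Optional[float] = None,
    n_sd: float = 3.0,
    quantile: float = 0.9,
) -> ExclusionResult:
    """Screen out molecules lacking an active acceptor dye.

    A molecule is donor-only iff its acceptor response under red (direct)
    excitation stays below ``threshold``.  By default the threshold is the
    pooled dark-frame acceptor level plus ``n_sd`` standard deviations.  The
    per-molecule statistic is the ``quantile`` of its red-frame acceptor
    intensities, which is robust to photobleaching partway through the
    movie.  Traces without red frames cannot be classified: they are
    retained and flagged, with a warning.
    """
    traces = list(traces)
    if threshold is None:
        dark = [
            tr.acceptor[tr.excitation == DARK]
            for tr in traces
            if np.any(tr.excitation == DARK)
        ]
        if dark:
            pooled = np.concatenate(dark)
            threshold = float(pooled.mean() + n_sd * pooled.std())
        else:
            threshold = 0.0
    kept, excluded, flagged = [], [], []
    for tr in traces:
        red = tr.acceptor[tr.excitation == RED]
        if len(red) == 0:
            flagged.append(tr)
            kept.append(tr)
            continue
        if np.quantile(red, quantile) <= threshold:
            excluded.append(tr)
        else:
            kept.append(tr)
    if flagged:
        warnings.warn(
            f"{len(flagged)} trace(s) have no red-excitation frames and could "
            "not be screened for donor-only molecules; retained",
            RuntimeWarning,
        )
    return ExclusionResult(kept=kept, excluded=excluded, flagged=flagged, threshold=threshold)


@dataclass
class FretHistogram:
    """Density-normalized histogram of framewise FRET efficiencies."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_molecules: int
    n_frames: int = 0
    components: Optional[list] = None  # [(weight, mean, sd), ...] once fitted

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def build_histogram(
    traces: Sequence[FretTrace],
    frames_per_molecule: int = 21,
    bin_width: float = 0.02,
    e_range: tuple = (-0.1, 1.1),
) -> FretHistogram:
    """Histogram the first green-excitation frames of each molecule.

    Each molecule contributes the E values of its first
    ``frames_per_molecule`` green frames (NaN frames dropped); the density
    integrates to 1.
    """
    values = []
    n_mol = 0
    for tr in traces:
        e = tr.efficiencies(GREEN)[:frames_per_molecule]
        e = e[np.isfinite(e)]
        if len(e):
            values.append(e)
            n_mol += 1
    if not values:
        raise InsufficientDataError("no usable FRET frames: empty histogram")
    all_e = np.concatenate(values)
    lo, hi = e_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    all_e = np.clip(all_e, lo, np.nextafter(hi, lo))
    density, edges = np.histogram(all_e, bins=edges, density=True)
    return FretHistogram(
        bin_edges=edges, density=density, n_molecules=n_mol, n_frames=len(all_e)
    )


# ---------------------------------------------------------------------------
# Gaussian mixture fit (least squares on the binned density)


def _mixture_density(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    k = len(theta) // 3
    out = np.zeros_like(x)
    for i in range(k):
        w, m, s = theta[3 * i : 3 * i + 3]
        out += w / (s * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((x - m) / s) ** 2)
    return out


@dataclass
class MixtureFitResults:
    """Sum-of-Gaussians fit to a FRET histogram.

    ``components`` are (weight, mean, sd) triples sorted by mean; each
    component integrates to its weight since the histogram density
    integrates to 1.
    """

    components: list
    rss: float
    converged: bool
    n_components: int
    seed: int

    @property
    def means(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _, _ in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([s for _, _, s in self.components])

    def thresholds(self) -> tuple:
        """Midpoints between adjacent component means (state boundaries)."""
        m = self.means
        return tuple((m[i] + m[i + 1]) / 2 for i in range(len(m) - 1))

    def summary(self) -> str:
        lines = [
            f"Gaussian mixture fit ({self.n_components} components, "
            f"rss={self.rss:.4g}, converged={self.converged})",
            f"  {'weight':>8} {'mean':>8} {'sd':>8}",
        ]
        for w, m, s in self.components:
            lines.append(f"  {w:8.4f} {m:8.4f} {s:8.4f}")
        return "\n".join(lines)


def fit_gaussian_mixture(
    hist: FretHistogram,
    n_components: int,
    seed: int = 0,
    n_starts: int = 10,
    sd_floor: float = 0.01,
) -> MixtureFitResults:
    """Least-squares fit of a weighted Gaussian sum to the binned density.

    Multi-start: peak-anchored and random initializations, plus a warm start
    from the (n-1)-component fit with a vanishing extra component — which
    makes the achieved rss non-increasing in ``n_components``.  Component
    SDs are floored at ``sd_floor`` to prevent delta collapse onto single
    bins.
    """
    if not 1 <= n_components <= 4:
        raise ParameterError(f"n_components must be in 1..4, got {n_components}")
    x = hist.bin_centers
    y = hist.density
    rng = np.random.default_rng(seed)

    starts = []
    # peak-anchored start: highest-density bins, greedily separated
    order = np.argsort(y)[::-1]
    peaks = []
    for idx in order:
        if all(abs(x[idx] - p) > 0.08 for p in peaks):
            peaks.append(x[idx])
        if len(peaks) == n_components:
            break
    while len(peaks) < n_components:
        peaks.append(rng.uniform(0.1, 0.9))
    theta0 = []
    for m in sorted(peaks):
        theta0 += [1.0 / n_components, m, 0.05]
    starts.append(np.array(theta0))
    # quantile-spread start
    qs = np.linspace(0.15, 0.85, n_components)
    starts.append(
        np.concatenate([[1.0 / n_components, q, 0.06] for q in qs])
    )
    # random starts
    while len(starts) < n_starts:
        theta = []
        for _ in range(n_components):
            theta += [
                rng.uniform(0.05, 1.0),
                rng.uniform(0.0, 1.0),
                10 ** rng.uniform(math.log10(max(sd_floor, 0.02)), math.log10(0.15)),
            ]
        starts.append(np.array(theta))
    # warm start from the smaller mixture
    if n_components > 1:
        prev = fit_gaussian_mixture(
            hist, n_components - 1, seed=seed, n_starts=n_starts, sd_floor=sd_floor
        )
        warm = []
        for w, m, s in prev.components:
            warm += [w, m, s]
        warm += [1e-6, float(np.clip(prev.means.mean() + 0.2, 0.0, 1.0)), 0.05]
        starts.append(np.array(warm))

    lb = np.tile([0.0, hist.bin_edges[0], sd_floor], n_components)
    ub = np.tile([2.0, hist.bin_edges[-1], 0.5], n_components)

    best, best_cost, any_success = None, np.inf, False
    for theta in starts:
        theta = np.clip(theta, lb, ub)
        try:
            res = least_squares(
                lambda th: _mixture_density(x, th) - y,
                theta,
                bounds=(lb, ub),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        if res.success:
            any_success = True
        if res.cost < best_cost:
            best_cost = res.cost
            best = res
    if best is None:
        raise RuntimeError("all mixture-fit starts failed")
    theta = best.x
    comps = sorted(
        [
            (float(theta[3 * i]), float(theta[3 * i + 1]), float(theta[3 * i + 2]))
            for i in range(n_components)
        ],
        key=lambda c: c[1],
    )
    return MixtureFitResults(
        components=comps,
        rss=float(2.0 * best.cost),
        converged=any_success,
        n_components=n_components,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# State assignment


@dataclass
class StateSegmentation:
    """Threshold-based low/mid/high state labels of one trace.

    Labels cover the green-excitation frames in order; dwell times are
    contiguous-run lengths times the frame interval (runs are counted
    within the green-frame series, ignoring the interleaved red/dark
    frames — block gaps are short relative to state dwell times).
    """

    thresholds: tuple
    labels: np.ndarray
    frame_interval: float
    dwells: list = field(default_factory=list)  # (state, duration_s)

    def occupancy(self) -> dict:
        n = len(self.labels)
        if n == 0:
            return {"low": math.nan, "mid": math.nan, "high": math.nan}
        return {s: float(np.sum(self.labels == s)) / n for s in ("low", "mid", "high")}


def assign_states(
    trace: FretTrace,
    thresholds: tuple,
    median_filter: bool = False,
) -> StateSegmentation:
    """Label each green frame low/mid/high by thresholding its efficiency.

    Ties at a boundary go to the lower state (E <= t_low -> low,
    E <= t_high -> mid, else high).  An optional 3-frame median filter
    suppresses single-frame shot-noise excursions before thresholding.
    NaN frames (no signal) are dropped.
    """
    t_low, t_high = thresholds
    if not (0 < t_low < t_high < 1):
        raise ParameterError(
            f"thresholds must satisfy 0 < low < high < 1, got ({t_low}, {t_high})"
        )
    e = trace.efficiencies(GREEN)
    e = e[np.isfinite(e)]
    if median_filter and len(e) >= 3:
        e = medfilt(e, kernel_size=3)
    labels = np.where(e <= t_low, "low", np.where(e <= t_high, "mid", "high"))
    dwells = []
    if len(labels):
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                dwells.append((str(labels[start]), (i - start) * trace.frame_interval))
                start = i
    return StateSegmentation(
        thresholds=(t_low, t_high),
        labels=labels,
        frame_interval=trace.frame_interval,
        dwells=dwells,
    )


def state_occupancy(
    traces: Sequence[FretTrace], thresholds: tuple, median_filter: bool = False
) -> dict:
    """Pooled low/mid/high occupancy over the green frames of a cohort."""
    counts = {"low": 0, "mid": 0, "high": 0}
    total = 0
    for tr in traces:
        seg = assign_states(tr, thresholds, median_filter=median_filter)
        for s in counts:
            counts[s] += int(np.sum(seg.labels == s))
        total += len(seg.labels)
    if total == 0:
        raise InsufficientDataError("no frames to compute occupancy from")
    return {s: counts[s] / total for s in counts}
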