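"""Synthetic data generators for every pipeline stage.

Three generators emulate the raw measurements the analysis consumes:

* :func:`generate_gel_timecourse` — EMSA lane tables.  Species fractions
  come from the kinetic model on the standard 8-point grid (0, 0.5, 3, 5,
  10, 15, 20, 30 min), are converted to Cy5 band intensities with a random
  per-lane scale factor and multiplicative lognormal band noise, and the
  cumulative RNA signal integrates an instantaneous rate
  r(t) = max(0, r0 + alpha*H(t) - beta*I(t)) — HG4 enhances and IG4
  suppresses transcription, with the rate clamped at zero so RNA is
  non-decreasing.

* :func:`generate_traces` — smFRET intensity traces.  Each molecule runs a
  continuous-time Markov chain over FRET states, sampled at the camera
  frame interval under an alternating green/red excitation scheme with dark
  separator frames; donor/acceptor intensities partition a total intensity
  by the framewise efficiency, with shot-like Gaussian noise, camera
  background, donor leakage into the acceptor channel, single-exponential
  photobleaching, and a planted fraction of donor-only molecules.

* :func:`generate_cohort` — multi-construct summaries.  Rate constants are
  monotone functions of mean loop length (equilibrium constant decreasing,
  HG4 conversion rate increasing) with lognormal jitter; per construct a
  noisy gel time course is generated, quantified, averaged over replicates
  and fitted, yielding the summary table the correlation ledger consumes.

Every generator takes an explicit seed and returns the ground truth next to
the data, so recovery tests never re-derive parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .gel import GelLane, mean_timecourse, quantify_table, transcription_rate
from .kinetics import (
    DEFAULT_TIME_GRID,
    KineticModel,
    KineticParams,
    solve_timecourse,
)
from .pqs import PQSDesign, build_pqs
from .smfret import DARK, GREEN, RED, FretTrace

__all__ = [
    "GelGeneratorConfig",
    "TraceGeneratorConfig",
    "CohortCoupling",
    "generate_gel_timecourse",
    "generate_traces",
    "generate_cohort",
    "ctmc_stationary",
]


# ---------------------------------------------------------------------------
# Gel time courses


@dataclass
class GelGeneratorConfig:
    """Configuration of the EMSA lane generator.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal band noise (0.05 = 5%, matching replicate scatter of the
    quantified gels).  ``rna_r0``, ``rna_alpha`` and ``rna_beta`` set the
    instantaneous transcription rate r(t) = max(0, r0 + alpha*H - beta*I)
    in normalized RNA units per minute.
    """

    params: KineticParams
    times: Sequence[float] = DEFAULT_TIME_GRID
    noise_cv: float = 0.05
    rna_r0: float = 0.005
    rna_alpha: float = 0.03
    rna_beta: float = 0.03
    n_replicates: int = 3
    lane_scale: float = 1000.0      # mean total Cy5 intensity per lane
    sybr_scale: float = 800.0       # mean total SYBR DNA+IG4+HG4 intensity
    initial: Sequence[float] = (1.0, 0.0, 0.0)
    construct_code: str = ""
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if len(t) == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ConfigError("times must be nonnegative and strictly increasing")
        if not 0 <= self.noise_cv < 1:
            raise ConfigError(f"noise_cv must be in [0, 1), got {self.noise_cv}")
        for name in ("rna_r0", "rna_alpha", "rna_beta"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.lane_scale <= 0 or self.sybr_scale <= 0:
            raise ConfigError("intensity scales must be positive")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def _cumulative_rna(config: GelGeneratorConfig, n_fine: int = 3001) -> np.ndarray:
    """Noise-free cumulative RNA at config.times.

    Integrates r(t) = max(0, r0 + alpha*H - beta*I) on a dense grid with the
    trapezoid rule and interpolates onto the sampling times.
    """
    times = np.asarray(config.times, dtype=float)
    t_max = float(times[-1]) if times[-1] > 0 else 1.0
    fine = np.linspace(0.0, t_max, n_fine)
    tc = solve_timecourse(config.params, fine, initial=config.initial)
    rate = np.clip(
        config.rna_r0 + config.rna_alpha * tc.hg4_frac - config.rna_beta * tc.ig4_frac,
        0.0,
        None,
    )
    cum = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * np.diff(fine))])
    return np.interp(times, fine, cum)


def generate_gel_timecourse(config: GelGeneratorConfig):
    """Generate raw gel lanes from the kinetic model.

    Returns ``(lanes, truth)`` where ``lanes`` is a list of
    :class:`~g4rloop.gel.GelLane` (one per replicate and time point) and
    ``truth`` records the generating parameters, the noise-free fractions
    and the noise-free normalized RNA curve.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    tc = solve_timecourse(config.params, times, initial=config.initial)
    fracs = tc.fractions()
    rna = _cumulative_rna(config)
    lanes = []
    for rep in range(config.n_replicates):
        for i, t in enumerate(times):
            cy5_scale = config.lane_scale * _lognormal_factor(rng, config.noise_cv)
            sybr_scale = config.sybr_scale * _lognormal_factor(rng, config.noise_cv)
            cy5 = fracs[i] * cy5_scale * _lognormal_factor(rng, config.noise_cv, size=3)
            sybr = fracs[i] * sybr_scale * _lognormal_factor(rng, config.noise_cv, size=3)
            sybr_rna = rna[i] * sybr_scale * _lognormal_factor(rng, config.noise_cv)
            lanes.append(
                GelLane(
                    time_min=float(t),
                    cy5_dna=float(cy5[0]),
                    cy5_ig4=float(cy5[1]),
                    cy5_hg4=float(cy5[2]),
                    sybr_rna=float(sybr_rna),
                    sybr_dna=float(sybr[0]),
                    sybr_ig4=float(sybr[1]),
                    sybr_hg4=float(sybr[2]),
                    construct_code=config.construct_code,
                    replicate_id=rep,
                )
            )
    truth = {
        "params": config.params,
        "times": times.tolist(),
        "fractions": fracs,
        "rna_norm": rna,
        "rna_coefficients": {
            "r0": config.rna_r0,
            "alpha": config.rna_alpha,
            "beta": config.rna_beta,
        },
        "noise_cv": config.noise_cv,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
    }
    return lanes, truth


# ---------------------------------------------------------------------------
# smFRET traces


@dataclass
class TraceGeneratorConfig:
    """Configuration of the CTMC smFRET trace generator.

    Default states loosely anchor the three FRET regimes of this system:
    low ~0.3 (duplex DNA), mid ~0.5 (HG4 / bare R-loop), high ~0.75 (IG4
    R-loop).  ``transition_rates`` is a (k, k) matrix of rates (s^-1) with
    off-diagonal entries the state-to-state rates; the default is a
    low <-> mid <-> high chain with 0.5 s^-1 steps (uniform stationary
    occupancy).
    """

    states: Sequence[tuple] = (
        ("low", 0.3, 0.05),
        ("mid", 0.5, 0.05),
        ("high", 0.75, 0.05),
    )
    transition_rates: Optional[np.ndarray] = None
    total_intensity: float = 1000.0     # mean photons/frame from an active pair
    background: float = 20.0            # mean camera background per channel
    background_sd: float = 5.0
    frame_interval: float = 0.1         # seconds
    bleach_rate: float = 0.01           # s^-1, joint single-exponential bleaching
    leakage: float = 0.05               # donor -> acceptor spectral leakage
    donor_only_fraction: float = 0.0
    n_molecules: int = 100
    n_cycles: int = 3                   # green(10), dark, red(10), dark per cycle
    green_frames: int = 10
    red_frames: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.transition_rates is None:
            k = len(self.states)
            q = np.zeros((k, k))
            for i in range(k - 1):
                q[i, i + 1] = 0.5
                q[i + 1, i] = 0.5
            self.transition_rates = q
        else:
            self.transition_rates = np.asarray(self.transition_rates, dtype=float)

    def validate(self) -> None:
        k = len(self.states)
        if k < 1:
            raise ConfigError("need at least one FRET state")
        for name, mean, sd in self.states:
            if not 0 <= mean <= 1:
                raise ConfigError(f"state {name!r} mean {mean} outside [0, 1]")
            if sd < 0:
                raise ConfigError(f"state {name!r} sd must be >= 0")
        q = self.transition_rates
        if q.shape != (k, k) or np.any(q < 0) or np.any(np.diag(q) != 0):
            raise ConfigError(
                "transition_rates must be (k, k) nonnegative with zero diagonal"
            )
        if not 0 <= self.leakage < 1:
            raise ConfigError(f"leakage must be in [0, 1), got {self.leakage}")
        if not 0 <= self.donor_only_fraction < 1:
            raise ConfigError("donor_only_fraction must be in [0, 1)")
        if self.bleach_rate < 0:
            raise ConfigError("bleach_rate must be >= 0")
        if self.frame_interval <= 0 or self.total_intensity <= 0:
            raise ConfigError("frame_interval and total_intensity must be positive")
        if self.n_molecules < 1 or self.n_cycles < 1:
            raise ConfigError("n_molecules and n_cycles must be >= 1")

    def excitation_pattern(self) -> np.ndarray:
        cycle = (
            [GREEN] * self.green_frames + [DARK] + [RED] * self.red_frames + [DARK]
        )
        return np.array(cycle * self.n_cycles, dtype=object)


def ctmc_stationary(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC from its rate matrix (off-diagonal
    rates; diagonal filled as negative row sums)."""
    k = q.shape[0]
    gen = q.copy().astype(float)
    np.fill_diagonal(gen, 0.0)
    np.fill_diagonal(gen, -gen.sum(axis=1))
    # solve pi @ gen = 0 with sum(pi) = 1
    a = np.vstack([gen.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _simulate_ctmc_path(
    q: np.ndarray, t_end: float, rng: np.random.Generator, pi0: np.ndarray
):
    """Jump times and states of one CTMC realization up to t_end."""
    k = q.shape[0]
    out_rates = q.sum(axis=1)
    state = int(rng.choice(k, p=pi0))
    jump_times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = out_rates[state]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        state = int(rng.choice(k, p=q[state] / rate))
        jump_times.append(t)
        states.append(state)
    return np.array(jump_times), np.array(states, dtype=int)


def generate_traces(config: TraceGeneratorConfig):
    """Simulate an smFRET molecule cohort.

    Returns ``(traces, truth)``; ``truth`` records per-molecule state paths
    at frame resolution, donor-only flags, bleach frames, the stationary
    occupancy of the CTMC and the full configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    exc = config.excitation_pattern()
    n_frames = len(exc)
    dt = config.frame_interval
    t_end = n_frames * dt
    q = config.transition_rates
    pi = ctmc_stationary(q)
    means = np.array([s[1] for s in config.states])
    sds = np.array([s[2] for s in config.states])
    i0 = config.total_intensity
    bg, bg_sd = config.background, config.background_sd
    frame_times = np.arange(n_frames) * dt

    traces, mol_truth = [], []
    for mol in range(config.n_molecules):
        donor_only = bool(rng.random() < config.donor_only_fraction)
        if config.bleach_rate > 0:
            t_bleach = rng.exponential(1.0 / config.bleach_rate)
        else:
            t_bleach = math.inf
        jump_t, jump_s = _simulate_ctmc_path(q, t_end, rng, pi)
        frame_state = jump_s[np.searchsorted(jump_t, frame_times, side="right") - 1]
        donor = np.empty(n_frames)
        acceptor = np.empty(n_frames)
        for f in range(n_frames):
            bleached = frame_times[f] >= t_bleach
            d_sig = a_sig = 0.0
            if not bleached:
                if exc[f] == GREEN:
                    if donor_only:
                        d_sig = i0
                    else:
                        e = float(np.clip(rng.normal(means[frame_state[f]],
                                                     sds[frame_state[f]]), 0.0, 1.0))
                        d_sig = i0 * (1.0 - e)
                        a_sig = i0 * e
                    a_sig += config.leakage * d_sig
                elif exc[f] == RED and not donor_only:
                    a_sig = i0
            d = d_sig + rng.normal(bg, bg_sd) + rng.normal(0.0, math.sqrt(max(d_sig, 0.0)))
            a = a_sig + rng.normal(bg, bg_sd) + rng.normal(0.0, math.sqrt(max(a_sig, 0.0)))
            donor[f] = max(d, 0.0)
            acceptor[f] = max(a, 0.0)
        traces.append(
            FretTrace(
                donor=donor,
                acceptor=acceptor,
                excitation=exc.copy(),
                frame_interval=dt,
                molecule_id=f"mol{mol:05d}",
            )
        )
        mol_truth.append(
            {
                "molecule_id": f"mol{mol:05d}",
                "donor_only": donor_only,
                "bleach_time_s": t_bleach,
                "frame_states": frame_state,
            }
        )
    truth = {
        "states": list(config.states),
        "stationary": pi,
        "leakage": config.leakage,
        "donor_only_fraction": config.donor_only_fraction,
        "molecules": mol_truth,
        "seed": config.seed,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# Multi-construct cohorts


@dataclass
class CohortCoupling:
    """Monotone maps from mean loop length L to rate constants.

    keq(L) = keq_base * exp(-keq_decay * (L - 1)) — the IG4 equilibrium
    constant falls with loop length (longer loops destabilize the
    intramolecular G4); k2(L) = k2_base * exp(k2_growth * (L - 1)) — the
    IG4 -> HG4 conversion accelerates with loop length.  k1 is held at a
    common formation rate; k1r follows from k1/keq.  ``jitter_cv`` adds
    lognormal construct-to-construct scatter to every rate.  RNase-H
    resistance of the IG4 R-loop is a saturating function of keq.
    """

    k1: float = 0.35                 # min^-1, IG4 R-loop formation
    keq_base: float = 10.0           # Keq at L = 1 (tight loops, stable IG4)
    keq_decay: float = 0.8           # per nt of mean loop length
    k2_base: float = 0.015           # min^-1 at L = 1
    k2_growth: float = 0.5           # per nt of mean loop length
    jitter_cv: float = 0.10
    resistance_halfsat: float = 2.0  # keq at 50% RNase-H resistance

    def rates_for(self, design: PQSDesign, rng: np.random.Generator) -> KineticParams:
        L = design.mean_loop_length
        keq = self.keq_base * math.exp(-self.keq_decay * (L - 1.0))
        k2 = self.k2_base * math.exp(self.k2_growth * (L - 1.0))
        k1 = self.k1 * _lognormal_factor(rng, self.jitter_cv)
        keq *= _lognormal_factor(rng, self.jitter_cv)
        k2 *= _lognormal_factor(rng, self.jitter_cv)
        return KineticParams(k1=float(k1), k1r=float(k1 / keq), k2=float(k2))

    def resistance_for(self, keq: float, rng: np.random.Generator) -> float:
        base = keq / (keq + self.resistance_halfsat)
        return float(np.clip(base * _lognormal_factor(rng, self.jitter_cv), 0.0, 1.0))


DEFAULT_COHORT_CODES = (
    "111", "112", "121", "211", "122", "212",
    "221", "113", "123", "133", "134", "144",
)


def generate_cohort(
    designs: Sequence[PQSDesign | str],
    coupling: Optional[CohortCoupling] = None,
    seed: int = 0,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    fit_n_starts: int = 8,
    rna_production: str = "level_30min",
):
    """Generate and analyze a multi-construct cohort end to end.

    For each design: draw loop-length-coupled rates, simulate a noisy gel
    time course, quantify it, average replicates, fit the irreversible
    kinetic scheme, and emit one summary row.  Returns ``(summaries, truth)``
    where ``summaries`` is a DataFrame with one row per construct (the
    correlation-ledger input) and ``truth`` maps construct codes to their
    generating parameters.

    ``rna_production`` selects the summary statistic: ``"level_30min"``
    (normalized RNA at the last time point, the default) or ``"rate"`` (OLS
    slope over time).
    """
    if len(designs) < 4:
        raise ConfigError(f"cohort needs >= 4 designs, got {len(designs)}")
    designs = [d if isinstance(d, PQSDesign) else build_pqs(d) for d in designs]
    coupling = coupling or CohortCoupling()
    rng = np.random.default_rng(seed)
    rows, truth = [], {}
    for design in designs:
        params = coupling.rates_for(design, rng)
        gel_seed = int(rng.integers(0, 2**31 - 1))
        config = GelGeneratorConfig(
            params=params,
            noise_cv=noise_cv,
            n_replicates=n_replicates,
            construct_code=design.code,
            seed=gel_seed,
        )
        lanes, gel_truth = generate_gel_timecourse(config)
        qdf = quantify_table(
            pd.DataFrame(
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
        )
        tc = mean_timecourse(qdf, construct=design.code)
        fit = KineticModel(tc).fit(n_starts=fit_n_starts, seed=gel_seed % (2**31 - 1))
        if rna_production == "rate":
            rna_stat = transcription_rate(tc.to_frame().rename(
                columns={"rna_level": "rna_norm"})).slope
        else:
            rna_stat = float(tc.rna_level[-1])
        ig4_level = float(tc.ig4_frac[-1])
        hg4_level = float(tc.hg4_frac[-1])
        ratio = hg4_level / ig4_level if ig4_level > 0 else math.nan
        true_keq = params.k1 / params.k1r
        resistance = coupling.resistance_for(true_keq, rng)
        fitted_keq = fit.params.k1 / fit.params.k1r if fit.params.k1r > 0 else math.nan
        rows.append(
            {
                "construct_code": design.code,
                "rna_production": rna_stat,
                "ig4_level": ig4_level,
                "hg4_level": hg4_level,
                "hg4_ig4_ratio": ratio,
                "loop_length_mean": design.mean_loop_length,
                "loop_variance": design.loop_variance,
                "k1": fit.params.k1,
                "k1r": fit.params.k1r,
                "k2": fit.params.k2,
                "keq": fitted_keq,
                "ig4_after_rnaseh": resistance * ig4_level,
                "fit_converged": fit.converged,
            }
        )
        truth[design.code] = {
            "params": params,
            "keq": true_keq,
            "rnaseh_resistance": resistance,
            "gel_truth": gel_truth,
        }
    return pd.DataFrame(rows), truth
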