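"""End-to-end pipeline orchestration (generate -> quantify -> fit -> correlate).

A :class:`RunConfig` (loadable from a YAML file) selects stages, inputs and
seeds.  Stages run in dependency order; each stage records its outputs and
captured warnings in the run report, and a stage failure marks downstream
stages skipped rather than raising.  Every run writes ``report.json`` with a
provenance record (config hash, seeds, package version) so identical
configs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlates import correlation_ledger, stability_proxy_relations
from .exceptions import ConfigError, G4RloopError, PipelineError
from .gel import (
    aggregate_replicates,
    quantify_table,
    replicate_timecourses,
    transcription_rate,
)
from .io import (
    read_lane_table,
    read_summary_table,
    read_timecourse,
    read_traces,
    write_quantified_table,
    write_summary_table,
)
from .kinetics import ModelId, compare_models, fit_kinetics
from .smfret import (
    build_histogram,
    correct_donor_leakage,
    estimate_leakage,
    exclude_donor_only,
    fit_gaussian_mixture,
    state_occupancy,
)
from .synth import (
    DEFAULT_COHORT_CODES,
    TraceGeneratorConfig,
    generate_cohort,
    generate_traces,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "STAGE_ORDER"]

#: Canonical stage execution order.
STAGE_ORDER = ("cohort", "quantify", "rate", "kinetics", "correlate", "smfret")


@dataclass
class RunConfig:
    """Pipeline run configuration.

    ``stages`` lists the stages to execute (any subset of
    :data:`STAGE_ORDER`); ``inputs`` maps stage names to input file paths
    when a stage does not consume the previous stage's in-memory output.
    """

    stages: tuple = ("cohort", "correlate")
    out_dir: str = "g4rloop_run"
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    # cohort generator options
    cohort_codes: tuple = DEFAULT_COHORT_CODES
    cohort_noise_cv: float = 0.05
    cohort_n_replicates: int = 3
    # kinetics options
    kinetics_model: str = "both"            # irreversible | reversible | both
    kinetics_n_starts: int = 20
    kinetics_max_time: Optional[float] = 30.0
    # smfret options
    smfret_bin_width: float = 0.02
    smfret_frames_per_molecule: int = 21
    smfret_n_components: int = 3
    smfret_n_molecules: int = 300
    smfret_donor_only_fraction: float = 0.2

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ConfigError(f"unknown stage(s) {unknown}; valid: {STAGE_ORDER}")
        if self.kinetics_model not in ("irreversible", "reversible", "both"):
            raise ConfigError(f"kinetics_model must be irreversible/reversible/both")
        out = Path(self.out_dir).resolve()
        for path in self.inputs.values():
            if Path(path).resolve().parent == out:
                raise ConfigError(
                    f"input {path} sits inside out_dir {self.out_dir}: outputs "
                    "must never overwrite inputs"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("stages", "cohort_codes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        d["cohort_codes"] = list(d["cohort_codes"])
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class StageReport:
    name: str
    status: str                 # "ok" | "failed" | "skipped"
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    error: Optional[str] = None


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(s.status == "ok" for s in self.stages)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": [asdict(s) for s in self.stages],
        }


def _stage_cohort(config: RunConfig, ctx: dict, out: Path) -> list:
    summaries, truth = generate_cohort(
        list(config.cohort_codes),
        seed=config.seed,
        noise_cv=config.cohort_noise_cv,
        n_replicates=config.cohort_n_replicates,
    )
    ctx["summary_df"] = summaries
    path = out / "cohort_summary.csv"
    write_summary_table(summaries, path)
    truth_path = out / "cohort_truth.json"
    serializable = {
        code: {
            "k1": rec["params"].k1,
            "k1r": rec["params"].k1r,
            "k2": rec["params"].k2,
            "keq": rec["keq"],
            "rnaseh_resistance": rec["rnaseh_resistance"],
        }
        for code, rec in truth.items()
    }
    truth_path.write_text(json.dumps(serializable, indent=2, sort_keys=True))
    return [str(path), str(truth_path)]


def _stage_quantify(config: RunConfig, ctx: dict, out: Path) -> list:
    if "quantify" in config.inputs:
        df = read_lane_table(config.inputs["quantify"])
    elif "lane_df" in ctx:
        df = ctx["lane_df"]
    else:
        raise PipelineError("quantify", "no lane table: provide inputs['quantify']")
    q = quantify_table(df)
    ctx["quantified_df"] = q
    path = out / "quantified_lanes.csv"
    write_quantified_table(q, path)
    agg = aggregate_replicates(q)
    agg_path = out / "quantified_aggregate.csv"
    agg.to_csv(agg_path, index=False)
    return [str(path), str(agg_path)]


def _stage_rate(config: RunConfig, ctx: dict, out: Path) -> list:
    if "quantified_df" not in ctx:
        raise PipelineError("rate", "no quantified table from a prior quantify stage")
    q = ctx["quantified_df"]
    rows = []
    for code, g in q.groupby("construct"):
        mean = g.groupby("time_min", as_index=False)["rna_norm"].mean()
        res = transcription_rate(mean)
        rows.append(
            {
                "construct": code,
                "rate_per_min": res.slope,
                "intercept": res.intercept,
                "r_value": res.r_value,
                "n": res.n,
            }
        )
    path = out / "transcription_rates.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [str(path)]


def _stage_kinetics(config: RunConfig, ctx: dict, out: Path) -> list:
    if "kinetics" in config.inputs:
        tcs = [read_timecourse(config.inputs["kinetics"])]
    elif "quantified_df" in ctx:
        q = ctx["quantified_df"]
        # joint fit over replicates per construct
        tcs = [
            replicate_timecourses(q, construct=code)
            for code in q["construct"].unique()
        ]
    else:
        raise PipelineError(
            "kinetics", "no time course: provide inputs['kinetics'] or run quantify"
        )
    reports = []
    for tc in tcs:
        code = (tc[0] if isinstance(tc, list) else tc).construct_code
        kwargs = dict(max_time=config.kinetics_max_time)
        if config.kinetics_model == "both":
            cmp = compare_models(
                tc, n_starts=config.kinetics_n_starts, seed=config.seed, **kwargs
            )
            rec = {
                "construct": code,
                "irreversible": cmp.irreversible.to_dict(),
                "reversible": cmp.reversible.to_dict(),
                "preferred": cmp.preferred.value,
                "delta_aic": cmp.delta_aic,
            }
        else:
            model_id = (
                ModelId.IRREVERSIBLE_HG4
                if config.kinetics_model == "irreversible"
                else ModelId.REVERSIBLE_HG4
            )
            fit = fit_kinetics(
                tc, model_id, n_starts=config.kinetics_n_starts,
                seed=config.seed, **kwargs,
            )
            rec = {"construct": code, "fit": fit.to_dict()}
        reports.append(rec)
    path = out / "kinetics_fits.json"
    path.write_text(json.dumps(reports, indent=2, sort_keys=True))
    return [str(path)]


def _stage_correlate(config: RunConfig, ctx: dict, out: Path) -> list:
    if "correlate" in config.inputs:
        df = read_summary_table(config.inputs["correlate"])
    elif "summary_df" in ctx:
        df = ctx["summary_df"]
    else:
        raise PipelineError(
            "correlate", "no summary table: provide inputs['correlate'] or run cohort"
        )
    ledger = correlation_ledger(df)
    matrix_path = out / "correlation_matrix.tsv"
    ledger.matrix.to_csv(matrix_path, sep="\t")
    report = {
        "ranking": [{"variable": v, "r": r} for v, r in ledger.ranking],
        "top_positive": ledger.top_positive,
        "strongest_negative": ledger.strongest_negative,
    }
    if "ig4_after_rnaseh" in df.columns:
        report["stability_proxy"] = stability_proxy_relations(df)
    rank_path = out / "correlation_report.json"
    rank_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    ctx["ledger"] = ledger
    return [str(matrix_path), str(rank_path)]


def _stage_smfret(config: RunConfig, ctx: dict, out: Path) -> list:
    if "smfret" in config.inputs:
        traces = read_traces(config.inputs["smfret"])
        truth = None
    else:
        tconf = TraceGeneratorConfig(
            n_molecules=config.smfret_n_molecules,
            donor_only_fraction=config.smfret_donor_only_fraction,
            seed=config.seed,
        )
        traces, truth = generate_traces(tconf)
    excl = exclude_donor_only(traces)
    if excl.excluded:
        leak = estimate_leakage(excl.excluded)
        kept = [correct_donor_leakage(tr, leak) for tr in excl.kept]
    else:
        leak = 0.0
        kept = excl.kept
    hist = build_histogram(
        kept,
        frames_per_molecule=config.smfret_frames_per_molecule,
        bin_width=config.smfret_bin_width,
    )
    mix = fit_gaussian_mixture(hist, config.smfret_n_components, seed=config.seed)
    occupancy = (
        state_occupancy(kept, mix.thresholds())
        if config.smfret_n_components == 3
        else None
    )
    report = {
        "n_traces": len(traces),
        "n_excluded_donor_only": excl.n_excluded,
        "excluded_fraction": excl.excluded_fraction,
        "leakage_coefficient": leak,
        "n_molecules_in_histogram": hist.n_molecules,
        "components": [
            {"weight": w, "mean": m, "sd": s} for w, m, s in mix.components
        ],
        "mixture_rss": mix.rss,
        "occupancy": occupancy,
    }
    if truth is not None:
        report["generator_stationary_occupancy"] = truth["stationary"].tolist()
    path = out / "smfret_report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return [str(path)]


_STAGE_FUNCS = {
    "cohort": _stage_cohort,
    "quantify": _stage_quantify,
    "rate": _stage_rate,
    "kinetics": _stage_kinetics,
    "correlate": _stage_correlate,
    "smfret": _stage_smfret,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    Returns the :class:`RunReport`; also writes it as ``report.json`` in
    ``config.out_dir``.  A failed stage is recorded with its error and all
    downstream stages are marked skipped.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_hash=config.config_hash(), seed=config.seed, version=__version__
    )
    ctx: dict = {}
    failed = False
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        if failed:
            report.stages.append(StageReport(name=stage, status="skipped"))
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                outputs = _STAGE_FUNCS[stage](config, ctx, out)
                report.stages.append(
                    StageReport(
                        name=stage,
                        status="ok",
                        outputs=outputs,
                        warnings=[str(w.message) for w in caught],
                    )
                )
            except G4RloopError as exc:
                failed = True
                report.stages.append(
                    StageReport(
                        name=stage,
                        status="failed",
                        error=str(exc),
                        warnings=[str(w.message) for w in caught],
                    )
                )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    (out / "config.yaml").write_text(config.to_yaml())
    return report
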