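import numpy as np
import pandas as pd
import pytest

from g4rloop.gel import quantify_table, replicate_timecourses
from g4rloop.io import write_lane_table
from g4rloop.kinetics import KineticParams, solve_timecourse
from g4rloop.synth import (
    GelGeneratorConfig,
    TraceGeneratorConfig,
    generate_gel_timecourse,
    generate_traces,
)

#: Reference rates used across tests (IG4 forms fast and reverts slowly,
#: HG4 conversion is slow) — the same values the fitting examples use.
REFERENCE_PARAMS = KineticParams(k1=0.3, k1r=0.05, k2=0.02)


@pytest.fixture(scope="session")
def reference_params():
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def reference_timecourse():
    return solve_timecourse(REFERENCE_PARAMS)


def make_quantified(params=REFERENCE_PARAMS, seed=0, noise_cv=0.05, n_replicates=3):
    config = GelGeneratorConfig(
        params=params, seed=seed, noise_cv=noise_cv, n_replicates=n_replicates
    )
    lanes, truth = generate_gel_timecourse(config)
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
    return quantify_table(df), truth


@pytest.fixture(scope="session")
def noisy_quantified():
    """Quantified 3-replicate gel table generated from the reference rates."""
    return make_quantified()


@pytest.fixture(scope="session")
def small_trace_cohort():
    """200 smFRET molecules with 20% donor-only, 5% leakage (seeded)."""
    config = TraceGeneratorConfig(
        n_molecules=200, donor_only_fraction=0.2, seed=11
    )
    return generate_traces(config)
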