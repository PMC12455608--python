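"""FRET efficiency, leakage correction, histograms, mixtures, state calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4rloop.exceptions import InsufficientDataError, ParameterError
from g4rloop.smfret import (
    FretTrace,
    assign_states,
    build_histogram,
    correct_donor_leakage,
    estimate_leakage,
    exclude_donor_only,
    fit_gaussian_mixture,
    fret_efficiency,
    leakage_coefficient,
    state_occupancy,
)


def green_trace(e_values, total=1000.0, molecule_id="m"):
    e = np.asarray(e_values, dtype=float)
    return FretTrace(
        donor=total * (1 - e), acceptor=total * e, molecule_id=molecule_id
    )


class TestEfficiency:
    def test_symmetric_point(self):
        assert fret_efficiency(500.0, 500.0) == pytest.approx(0.5)

    def test_donor_only_is_zero(self):
        assert fret_efficiency(800.0, 0.0) == 0.0

    def test_dark_frame_is_missing_not_zero(self):
        assert math.isnan(fret_efficiency(0.0, 0.0))

    def test_bounded_on_random_pairs(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1e4, size=10_000)
        a = rng.uniform(0, 1e4, size=10_000)
        e = fret_efficiency(d, a)
        assert np.all((e >= 0) & (e <= 1))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 1e4), st.floats(0.1, 1e4), st.floats(0.01, 1e3))
    def test_scale_invariance(self, d, a, c):
        assert fret_efficiency(c * d, c * a) == pytest.approx(
            fret_efficiency(d, a), rel=1e-12
        )


class TestLeakage:
    def test_zero_leakage_is_identity(self):
        tr = green_trace([0.2, 0.5, 0.8])
        out = correct_donor_leakage(tr, 0.0)
        assert np.array_equal(out.acceptor, tr.acceptor)
        assert np.array_equal(out.donor, tr.donor)

    def test_inverts_donor_only_apparent_efficiency(self):
        # donor-only molecule showing apparent E = 0.1 from leakage
        l_true = 0.1 / 0.9
        donor = np.full(50, 900.0)
        acceptor = l_true * donor
        tr = FretTrace(donor=donor, acceptor=acceptor)
        assert np.nanmean(tr.efficiencies()) == pytest.approx(0.1, abs=1e-12)
        corrected = correct_donor_leakage(tr, leakage_coefficient(0.1))
        assert np.nanmax(np.abs(corrected.acceptor)) < 1e-9

    def test_never_negative_acceptor(self):
        tr = green_trace([0.05, 0.1])
        out = correct_donor_leakage(tr, 0.5)
        assert np.all(out.acceptor >= 0)

    def test_increasing_leakage_weakly_decreases_efficiency(self):
        tr = green_trace([0.3, 0.5, 0.9])
        prev = correct_donor_leakage(tr, 0.0).efficiencies()
        for l in (0.05, 0.1, 0.2):
            cur = correct_donor_leakage(tr, l).efficiencies()
            assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_invalid_coefficient_rejected(self):
        with pytest.raises(ParameterError):
            correct_donor_leakage(green_trace([0.5]), 1.0)
        with pytest.raises(ParameterError):
            leakage_coefficient(1.0)


def alternating_trace(accept_red, n_cycles=2, molecule_id="m"):
    """10 green + dark + 10 red + dark cycles with constant channel levels."""
    exc, donor, acceptor = [], [], []
    for _ in range(n_cycles):
        for lab, d, a in (
            ("green", 700.0, 300.0),
            ("dark", 5.0, 5.0),
            ("red", 5.0, accept_red),
            ("dark", 5.0, 5.0),
        ):
            n = 10 if lab in ("green", "red") else 1
            exc += [lab] * n
            donor += [d] * n
            acceptor += [a] * n
    return FretTrace(
        donor=donor, acceptor=acceptor, excitation=np.array(exc, dtype=object),
        molecule_id=molecule_id,
    )


class TestDonorOnlyExclusion:
    def test_zero_red_response_excluded(self):
        good = alternating_trace(900.0, molecule_id="good")
        dead = alternating_trace(5.0, molecule_id="dead")
        res = exclude_donor_only([good, dead])
        assert [t.molecule_id for t in res.excluded] == ["dead"]
        assert [t.molecule_id for t in res.kept] == ["good"]

    def test_no_red_frames_flagged_and_retained(self):
        tr = green_trace([0.3, 0.5], molecule_id="allgreen")
        with pytest.warns(RuntimeWarning):
            res = exclude_donor_only([tr, alternating_trace(900.0)])
        assert any(t.molecule_id == "allgreen" for t in res.flagged)
        assert any(t.molecule_id == "allgreen" for t in res.kept)

    def test_recovers_planted_donor_only_fraction(self, small_trace_cohort):
        traces, truth = small_trace_cohort
        planted = np.mean([m["donor_only"] for m in truth["molecules"]])
        res = exclude_donor_only(traces)
        assert abs(res.excluded_fraction - planted) <= 0.03


class TestHistogram:
    def test_single_delta_population(self):
        traces = [green_trace([0.5] * 21, molecule_id=str(i)) for i in range(5)]
        hist = build_histogram(traces)
        assert hist.density.sum() * hist.bin_width == pytest.approx(1.0)
        assert np.count_nonzero(hist.density) == 1

    def test_two_equal_delta_populations(self):
        traces = [green_trace([0.2] * 21, molecule_id="a"),
                  green_trace([0.8] * 21, molecule_id="b")]
        hist = build_histogram(traces)
        occupied = hist.density[hist.density > 0] * hist.bin_width
        assert occupied == pytest.approx([0.5, 0.5])

    def test_density_matches_gaussian_law_of_large_numbers(self):
        rng = np.random.default_rng(3)
        e = np.clip(rng.normal(0.3, 0.05, size=100_000), 0, 1)
        traces = [green_trace(e[i * 20 : (i + 1) * 20], molecule_id=str(i))
                  for i in range(5000)]
        hist = build_histogram(traces, frames_per_molecule=20)
        x = hist.bin_centers
        ref = np.exp(-0.5 * ((x - 0.3) / 0.05) ** 2) / (0.05 * math.sqrt(2 * math.pi))
        assert np.max(np.abs(hist.density - ref)) < 0.05 * ref.max()

    def test_empty_cohort_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_histogram([])

    def test_integrates_to_one_for_any_bin_width(self):
        traces = [green_trace(np.linspace(0.1, 0.9, 21), molecule_id=str(i))
                  for i in range(10)]
        for bw in (0.01, 0.02, 0.05):
            hist = build_histogram(traces, bin_width=bw)
            assert hist.density.sum() * hist.bin_width == pytest.approx(1.0)


def synthetic_histogram(components, n=200_000, seed=0):
    rng = np.random.default_rng(seed)
    parts = []
    for w, m, s in components:
        parts.append(rng.normal(m, s, size=int(n * w)))
    e = np.clip(np.concatenate(parts), 0, 1)
    traces = [green_trace(e[i * 50 : (i + 1) * 50], molecule_id=str(i))
              for i in range(len(e) // 50)]
    return build_histogram(traces, frames_per_molecule=50)


class TestMixtureFit:
    def test_single_component_recovery(self):
        hist = synthetic_histogram([(1.0, 0.30, 0.05)])
        fit = fit_gaussian_mixture(hist, 1, seed=0)
        assert fit.means[0] == pytest.approx(0.30, abs=0.01)

    def test_two_component_weights(self):
        hist = synthetic_histogram([(0.5, 0.25, 0.05), (0.5, 0.75, 0.05)])
        fit = fit_gaussian_mixture(hist, 2, seed=0)
        assert fit.means == pytest.approx([0.25, 0.75], abs=0.01)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=0.05)

    def test_overfitting_single_gaussian_does_not_hurt_rss(self):
        hist = synthetic_histogram([(1.0, 0.40, 0.06)])
        one = fit_gaussian_mixture(hist, 1, seed=1)
        two = fit_gaussian_mixture(hist, 2, seed=1)
        assert two.rss <= one.rss + 1e-12

    def test_rss_non_increasing_in_components(self):
        hist = synthetic_histogram(
            [(0.4, 0.3, 0.05), (0.35, 0.5, 0.05), (0.25, 0.75, 0.05)]
        )
        rss = [fit_gaussian_mixture(hist, k, seed=2).rss for k in (1, 2, 3, 4)]
        assert np.all(np.diff(rss) <= 1e-12)

    def test_components_sorted_by_mean(self):
        hist = synthetic_histogram([(0.3, 0.7, 0.05), (0.7, 0.2, 0.05)])
        fit = fit_gaussian_mixture(hist, 2, seed=0)
        assert np.all(np.diff(fit.means) > 0)


class TestStateAssignment:
    def test_constant_high_trace(self):
        tr = green_trace([0.9] * 30)
        seg = assign_states(tr, (0.4, 0.65))
        assert set(seg.labels) == {"high"}
        assert seg.dwells == [("high", pytest.approx(3.0))]

    def test_square_wave_dwells(self):
        e = ([0.3] * 10 + [0.7] * 10) * 3
        seg = assign_states(green_trace(e), (0.5, 0.95))
        states, durations = zip(*seg.dwells)
        assert all(d == pytest.approx(1.0) for d in durations)
        assert states == ("low", "mid") * 3

    def test_boundary_ties_go_to_lower_state(self):
        tr = green_trace([0.4, 0.65])
        seg = assign_states(tr, (0.4, 0.65))
        assert list(seg.labels) == ["low", "mid"]

    def test_median_filter_suppresses_single_frame_spikes(self):
        e = [0.3] * 10
        e[5] = 0.9
        seg = assign_states(green_trace(e), (0.5, 0.7), median_filter=True)
        assert set(seg.labels) == {"low"}

    def test_occupancy_recovers_ctmc_stationary(self, small_trace_cohort):
        traces, truth = small_trace_cohort
        res = exclude_donor_only(traces)
        leak = estimate_leakage(res.excluded)
        kept = [correct_donor_leakage(t, leak) for t in res.kept]
        occ = state_occupancy(kept, (0.4, 0.625))
        stationary = truth["stationary"]
        for i, name in enumerate(("low", "mid", "high")):
            assert abs(occ[name] - stationary[i]) <= 0.05
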