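"""Kinetic scheme: rate equations, solutions, fitting, model comparison."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from g4rloop.exceptions import ParameterError, UnderDeterminedError
from g4rloop.gel import replicate_timecourses
from g4rloop.kinetics import (
    KineticModel,
    KineticParams,
    ModelId,
    SpeciesTimeCourse,
    compare_models,
    equilibrium_constant,
    fit_kinetics,
    rate_equations,
    solve_timecourse,
    _rate_matrix,
)
from conftest import REFERENCE_PARAMS, make_quantified

TIME_GRID = np.array([0.0, 0.5, 3.0, 5.0, 10.0, 15.0, 20.0, 30.0])


class TestRateEquations:
    def test_pure_dna_initial_flux(self):
        p = KineticParams(k1=0.7, k1r=0.2, k2=0.3)
        d = rate_equations((1.0, 0.0, 0.0), p)
        assert d == pytest.approx([-0.7, 0.7, 0.0])

    def test_hg4_absorbing_under_irreversible_model(self):
        p = KineticParams(k1=0.7, k1r=0.2, k2=0.3)
        assert rate_equations((0.0, 0.0, 1.0), p) == pytest.approx([0.0, 0.0, 0.0])

    def test_mixed_state_hand_arithmetic(self):
        p = KineticParams(k1=0.2, k1r=0.1, k2=0.05)
        d = rate_equations((0.5, 0.3, 0.2), p)
        assert d == pytest.approx([-0.07, 0.055, 0.015], abs=1e-12)

    def test_derivatives_conserve_mass(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rates = 10.0 ** rng.uniform(-3, 1, size=4)
            p = KineticParams(*rates)
            state = rng.dirichlet(np.ones(3))
            assert abs(rate_equations(state, p).sum()) < 1e-12

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterError):
            KineticParams(k1=-0.1, k1r=0.1, k2=0.1)


class TestSolveTimecourse:
    def test_initial_condition(self):
        tc = solve_timecourse(REFERENCE_PARAMS, [0.0])
        assert tc.fractions()[0] == pytest.approx([1.0, 0.0, 0.0])

    def test_no_forward_flux_stays_duplex(self):
        p = KineticParams(k1=0.0, k1r=0.3, k2=0.2)
        tc = solve_timecourse(p, TIME_GRID)
        assert np.allclose(tc.dna_frac, 1.0, atol=1e-9)

    def test_two_state_equilibrium_limit(self):
        # k2 = 0, k1 = k1r: D relaxes to one half
        p = KineticParams(k1=0.4, k1r=0.4, k2=0.0)
        tc = solve_timecourse(p, [0.0, 1e3 / 0.8])
        assert tc.dna_frac[-1] == pytest.approx(0.5, abs=1e-9)
        assert tc.hg4_frac[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_closed_form_matches_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            k2r = 0.0 if rng.random() < 0.5 else 10.0 ** rng.uniform(-3, 1)
            p = KineticParams(*(10.0 ** rng.uniform(-3, 1, size=3)), k2r=k2r or None)
            tc = solve_timecourse(p, TIME_GRID, method="closed_form")
            A = _rate_matrix(p)
            oracle = np.stack([expm(A * t) @ [1.0, 0.0, 0.0] for t in TIME_GRID])
            assert np.max(np.abs(tc.fractions() - oracle)) < 1e-8

    def test_closed_form_matches_numeric_integrator(self):
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(30):
            p = KineticParams(*(10.0 ** rng.uniform(-3, 1, size=3)))
            a = solve_timecourse(p, TIME_GRID, method="closed_form").fractions()
            b = solve_timecourse(p, TIME_GRID, method="numeric").fractions()
            worst = max(worst, float(np.max(np.abs(a - b))))
        assert worst < 1e-6

    def test_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            p = KineticParams(*(10.0 ** rng.uniform(-3, 1, size=4)))
            tc = solve_timecourse(p, TIME_GRID)
            total = tc.fractions().sum(axis=1)
            assert np.max(np.abs(total - 1.0)) < 1e-9

    def test_hg4_monotone_under_irreversible_model(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 30, 61)
        for _ in range(20):
            p = KineticParams(*(10.0 ** rng.uniform(-3, 1, size=3)))
            tc = solve_timecourse(p, t)
            assert np.all(np.diff(tc.hg4_frac) >= -1e-12)

    def test_degenerate_eigenvalues_fall_back_to_numeric(self):
        # all rates zero: triple eigenvalue at 0 — must not crash
        p = KineticParams(k1=0.0, k1r=0.0, k2=0.0)
        tc = solve_timecourse(p, TIME_GRID)
        assert np.allclose(tc.dna_frac, 1.0)

    def test_custom_initial_condition(self):
        # pre-folded G4 experiments start with IG4 present
        p = KineticParams(k1=0.0, k1r=0.0, k2=0.0)
        tc = solve_timecourse(p, [0.0, 5.0], initial=(0.4, 0.6, 0.0))
        assert tc.ig4_frac[-1] == pytest.approx(0.6)


class TestEquilibriumConstant:
    def test_ratio(self):
        assert equilibrium_constant(KineticParams(0.3, 0.05, 0.02)) == pytest.approx(6.0)
        assert equilibrium_constant(KineticParams(0.2, 0.2, 0.1)) == pytest.approx(1.0)

    def test_zero_reverse_rate_is_infinite_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert math.isinf(equilibrium_constant(KineticParams(0.3, 0.0, 0.02)))

    def test_ranking_matches_two_state_plateau_oracle(self):
        # with k2 forced to 0, D(inf) = k1r/(k1+k1r) = 1/(1+Keq): ranking by
        # Keq must invert the ranking by simulated long-time D
        rng = np.random.default_rng(5)
        keqs, d_inf = [], []
        for _ in range(10):
            k1, k1r = 10.0 ** rng.uniform(-2, 1, size=2)
            p = KineticParams(k1=k1, k1r=k1r, k2=0.0)
            keqs.append(equilibrium_constant(p))
            t_eq = 1e3 / (k1 + k1r)
            d_inf.append(solve_timecourse(p, [0.0, t_eq]).dna_frac[-1])
        assert np.array_equal(np.argsort(keqs), np.argsort(d_inf)[::-1])


class TestFit:
    def test_noise_free_recovery(self, reference_timecourse):
        fit = fit_kinetics(reference_timecourse, n_starts=8, seed=1)
        assert fit.converged
        est = fit.params
        for name in ("k1", "k1r", "k2"):
            true = getattr(REFERENCE_PARAMS, name)
            assert abs(getattr(est, name) - true) / true < 1e-3

    def test_degenerate_no_reaction_data(self):
        tc = SpeciesTimeCourse(
            times=TIME_GRID,
            dna_frac=np.ones(8),
            ig4_frac=np.zeros(8),
            hg4_frac=np.zeros(8),
        )
        fit = fit_kinetics(tc, n_starts=6, seed=0)
        assert fit.rss < 1e-10
        # the fitted scheme must predict no reaction: either k1 ~ 0 or any
        # formed IG4 reverts instantly (k1/k1r ~ 0)
        pred = fit.fittedvalues
        assert np.max(pred.ig4_frac + pred.hg4_frac) < 1e-5

    def test_under_determined_rejected(self):
        tc = SpeciesTimeCourse(
            times=[0.0, 5.0],
            dna_frac=[1.0, 0.5],
            ig4_frac=[0.0, 0.4],
            hg4_frac=[0.0, 0.1],
        )
        with pytest.raises(UnderDeterminedError):
            KineticModel(tc)

    def test_max_time_excludes_plateau_points(self):
        t = np.append(TIME_GRID, 45.0)
        tc = solve_timecourse(REFERENCE_PARAMS, t)
        model = KineticModel(tc)  # default max_time=30
        assert model.data.times[-1] == 30.0
        model_all = KineticModel(tc, max_time=None)
        assert model_all.data.times[-1] == 45.0

    def test_nested_models_rss_inequality(self, noisy_quantified):
        q, _ = noisy_quantified
        reps = replicate_timecourses(q)
        cmp = compare_models(reps, n_starts=5, seed=3)
        assert cmp.reversible.rss <= cmp.irreversible.rss + 1e-12

    def test_recovery_with_noise(self):
        # 5% multiplicative noise, 3 replicates averaged, 20 datasets:
        # median relative error of k1 and k2 well identified
        from g4rloop.gel import mean_timecourse

        errs = []
        for seed in range(20):
            q, _ = make_quantified(seed=seed)
            fit = fit_kinetics(mean_timecourse(q), n_starts=6, seed=seed)
            errs.append(
                [
                    abs(fit.params.k1 - 0.3) / 0.3,
                    abs(fit.params.k2 - 0.02) / 0.02,
                ]
            )
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.15)

    def test_summary_and_diagnostics(self, reference_timecourse):
        fit = fit_kinetics(reference_timecourse, n_starts=6, seed=1)
        text = fit.summary()
        assert "k1" in text and "AIC" in text and "Keq" in text
        assert fit.n_obs == 24
        assert fit.bse is None or len(fit.bse) == 3
        assert fit.resid.shape == (8, 3)


class TestModelComparison:
    def test_noise_free_prefers_true_irreversible(self, reference_timecourse):
        cmp = compare_models(reference_timecourse, n_starts=5, seed=0)
        assert cmp.preferred is ModelId.IRREVERSIBLE_HG4

    def test_prefers_reversible_when_back_conversion_strong(self):
        truth = KineticParams(k1=0.3, k1r=0.05, k2=0.1, k2r=0.1)
        tc = solve_timecourse(truth, TIME_GRID)
        cmp = compare_models(tc, n_starts=6, seed=0)
        assert cmp.preferred is ModelId.REVERSIBLE_HG4

    def test_equal_rss_penalizes_extra_parameter_by_two(self, reference_timecourse):
        cmp = compare_models(reference_timecourse, n_starts=4, seed=0)
        # noise-free data: both schemes reach rss ~ 0 at k2r = 0; the AIC
        # difference is then the parameter-count penalty
        if cmp.reversible.rss == pytest.approx(cmp.irreversible.rss, abs=1e-12):
            assert cmp.delta_aic == pytest.approx(2.0, abs=0.2)
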