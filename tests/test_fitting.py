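"""Estimation layer: steady-state Hill fits, normalizations, IC50 fits,
competition-model fits with bootstrap CIs, and model comparison."""

import numpy as np
import pandas as pd
import pytest

from bindfit import (
    CompetitionDataset,
    CompetitionSystem,
    EquilibriumParameters,
    ExperimentDesign,
    FitError,
    bound_fraction_no_competitor,
    cheng_prusoff_ki,
    compare_models,
    fit_competition_model,
    fit_ic50,
    fit_steady_state,
    generate_competition,
    generate_dose_response,
    hill_binding,
    normalize_fraction_of_calculated_zero,
    normalize_percent_of_reference,
    wang_competition_curve,
)

LADDER = (0.1, 0.32, 1.0, 3.2, 10.0, 32.0, 100.0)


class TestFitSteadyState:
    def test_noiseless_round_trip_on_dilution_ladder(self):
        truth = EquilibriumParameters(bmax=1.0, kd=10.4, hill=1.0)
        conc = np.array(LADDER)
        df = pd.DataFrame({"conc": conc, "replicate": 0,
                           "signal": hill_binding(conc, truth)})
        fit = fit_steady_state(df)
        assert fit.params.kd == pytest.approx(10.4, rel=1e-6)
        assert fit.params.bmax == pytest.approx(1.0, rel=1e-6)
        assert fit.params.hill == pytest.approx(1.0, rel=1e-6)
        assert not fit.extrapolated_bmax

    def test_all_zero_signal_raises(self):
        df = pd.DataFrame({"conc": LADDER, "replicate": 0, "signal": 0.0})
        with pytest.raises(FitError):
            fit_steady_state(df)

    def test_too_few_concentrations_raises(self):
        df = pd.DataFrame({"conc": [1.0, 10.0, 100.0], "replicate": 0,
                           "signal": [0.1, 0.5, 0.9]})
        with pytest.raises(FitError, match="4 distinct"):
            fit_steady_state(df)

    def test_noisy_triplicate_recovery(self):
        truth = EquilibriumParameters(bmax=1.0, kd=10.4, hill=1.0)
        design = ExperimentDesign(mode="steady_state", equilibrium=truth,
                                  concentrations=LADDER, noise_sd=0.03,
                                  n_replicates=3, seed=21)
        fit = fit_steady_state(generate_dose_response(design))
        assert fit.params.kd == pytest.approx(10.4, rel=0.15)
        assert abs(fit.params.hill - 1.0) < 0.2
        assert fit.n_replicates == 3
        assert fit.kd_sem is not None and fit.kd_sem > 0


class TestNormalizations:
    def test_percent_of_reference(self):
        out = normalize_percent_of_reference([2.0, 1.0], 2.0)
        assert np.allclose(out, [100.0, 50.0])

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_percent_of_reference([1.0], 0.0)

    def test_ic50_is_scale_invariant_under_normalization(self):
        sys_i = CompetitionSystem(0.5, 0.05, 10.4, 300.0)
        x = np.logspace(0, 6, 30)
        y = np.atleast_1d(wang_competition_curve(sys_i, x))
        raw = CompetitionDataset(x, y)
        pct = CompetitionDataset(x, normalize_percent_of_reference(y, y[0]),
                                 normalization="percent_of_zero_competitor")
        assert fit_ic50(raw).ic50 == pytest.approx(fit_ic50(pct).ic50, rel=1e-6)

    def test_calculated_zero_maps_measurement_onto_isotherm(self):
        sys_i = CompetitionSystem(64, 50, 10.4, 200)
        v0 = 8742.0  # arbitrary band intensity at zero competitor
        out = normalize_fraction_of_calculated_zero([v0, v0 / 2], sys_i)
        assert out[0] == pytest.approx(0.567782169545165, rel=1e-9)
        assert out[1] == pytest.approx(out[0] / 2)

    def test_calculated_zero_is_scale_invariant(self):
        sys_i = CompetitionSystem(64, 50, 10.4, 200)
        vals = np.array([5.0, 4.0, 1.0])
        assert np.allclose(
            normalize_fraction_of_calculated_zero(vals, sys_i),
            normalize_fraction_of_calculated_zero(vals * 37.2, sys_i))

    def test_no_receptor_reference_rejected(self):
        sys_i = CompetitionSystem(64, 1e-300, 10.4, 200)
        with pytest.raises(ValueError, match="zero"):
            normalize_fraction_of_calculated_zero([1.0], sys_i)


class TestFitIc50:
    def test_flat_data_rejected(self):
        ds = CompetitionDataset(np.logspace(0, 4, 10), np.full(10, 0.5))
        with pytest.raises(FitError, match="transition"):
            fit_ic50(ds)

    def test_no_depletion_ic50_inverts_to_kb(self):
        kb = 200.0
        sys_i = CompetitionSystem(32.0, 0.05, 10.4, kb)
        x = np.unique(np.concatenate([[0.0], np.logspace(0, 6, 25)]))
        y = np.atleast_1d(wang_competition_curve(sys_i, x))
        fit = fit_ic50(CompetitionDataset(x, y))
        ki = cheng_prusoff_ki(fit.ic50, 32.0, 10.4)
        assert ki == pytest.approx(kb, rel=0.01)

    def test_noisy_ic50_within_ten_percent_of_noiseless(self):
        sys_i = CompetitionSystem(32.0, 0.05, 10.4, 200.0)
        x = np.unique(np.concatenate([[0.0], np.logspace(0, 6, 25)]))
        y = np.atleast_1d(wang_competition_curve(sys_i, x))
        clean = fit_ic50(CompetitionDataset(x, y)).ic50
        rng = np.random.default_rng(17)
        noisy = y + rng.normal(0, 0.02 * y[0], y.size)
        assert fit_ic50(CompetitionDataset(x, noisy)).ic50 == pytest.approx(
            clean, rel=0.10)


class TestFitCompetitionModel:
    def test_noiseless_recovery_at_displacement_design(self, competitor_grid):
        truth = CompetitionSystem(64, 50, 10.4, 1060.0)
        y = np.atleast_1d(wang_competition_curve(truth, competitor_grid))
        ds = CompetitionDataset(competitor_grid, y)
        res = fit_competition_model(ds, CompetitionSystem(64, 50, 10.4, 500.0),
                                    "competitive", n_boot=0)
        assert res.kb == pytest.approx(1060.0, rel=1e-4)

    def test_noisy_triplicate_ci_contains_truth(self):
        truth = CompetitionSystem(64, 50, 10.4, 1060.0)
        design = ExperimentDesign(mode="competition", system=truth,
                                  noise_sd=0.05, n_replicates=3, seed=101)
        ds = generate_competition(design)
        res = fit_competition_model(ds, truth, "competitive",
                                    n_boot=300, seed=7)
        lo, hi = res.kb_ci
        assert lo < 1060.0 < hi
        assert lo < res.kb < hi

    def test_bootstrap_is_deterministic_given_seed(self, competitor_grid):
        truth = CompetitionSystem(64, 50, 10.4, 1060.0)
        design = ExperimentDesign(mode="competition", system=truth,
                                  noise_sd=0.05, n_replicates=3, seed=3)
        ds = generate_competition(design)
        r1 = fit_competition_model(ds, truth, "competitive", n_boot=50, seed=5)
        r2 = fit_competition_model(ds, truth, "competitive", n_boot=50, seed=5)
        assert r1.kb == r2.kb and r1.kb_ci == r2.kb_ci

    def test_percent_normalized_data_fits_identically(self, competitor_grid):
        truth = CompetitionSystem(64, 50, 10.4, 1060.0)
        y = np.atleast_1d(wang_competition_curve(truth, competitor_grid))
        y0 = bound_fraction_no_competitor(truth)
        pct = CompetitionDataset(competitor_grid,
                                 normalize_percent_of_reference(y, y0),
                                 normalization="percent_of_zero_competitor")
        res = fit_competition_model(pct, truth, "competitive", n_boot=0)
        assert res.kb == pytest.approx(1060.0, rel=1e-4)

    def test_no_displacement_raises(self, competitor_grid):
        flat = np.full(competitor_grid.size, 0.57)
        ds = CompetitionDataset(competitor_grid, flat)
        with pytest.raises(FitError, match="no displacement"):
            fit_competition_model(ds, CompetitionSystem(64, 50, 10.4, 500.0),
                                  "competitive", n_boot=0)

    def test_affinity_shift_truth_misfits_competitive_at_plateau(self):
        # a competitive fit to affinity-shift data cannot reproduce the
        # non-zero plateau: it leaves a systematic residual wave, positive
        # at the top of the competitor grid
        from bindfit import AffinityShiftParameters, affinity_shift_competition
        sys_i = CompetitionSystem(64, 50, 10.4, 200.0)
        x = np.array([0.0, 100.0, 400.0, 1600.0, 25000.0, 100000.0])
        y = np.atleast_1d(affinity_shift_competition(
            AffinityShiftParameters(sys_i, 5.0), x))
        ds = CompetitionDataset(x, y)
        res = fit_competition_model(ds, sys_i, "competitive", n_boot=0)
        fitted = np.atleast_1d(wang_competition_curve(
            CompetitionSystem(64, 50, 10.4, res.kb), x))
        resid = y - fitted
        assert np.max(np.abs(resid)) > 0.05
        assert resid[-1] > 0.05

    def test_shift_model_round_trip(self, competitor_grid):
        from bindfit import AffinityShiftParameters, affinity_shift_competition
        sys_i = CompetitionSystem(64, 50, 10.4, 200.0)
        y = np.atleast_1d(affinity_shift_competition(
            AffinityShiftParameters(sys_i, 5.0), competitor_grid))
        ds = CompetitionDataset(competitor_grid, y)
        res = fit_competition_model(ds, sys_i, "affinity_shift", n_boot=0)
        assert res.kb == pytest.approx(200.0, rel=1e-3)
        assert res.alpha == pytest.approx(5.0, rel=1e-3)


class TestCompareModels:
    def test_zero_residual_tie_is_ambiguous(self, competitor_grid):
        # without depletion the two model families coincide, so noiseless
        # data is fit with (numerically) zero residual by both: no verdict
        sys_i = CompetitionSystem(0.05, 0.005, 10.4, 200.0)
        y = np.atleast_1d(wang_competition_curve(sys_i, competitor_grid))
        ds = CompetitionDataset(competitor_grid, y)
        cmp = compare_models(ds, sys_i)
        assert cmp.verdict == "ambiguous"
        assert cmp.p_value == 1.0

    def test_competitive_truth_favors_competitive(self):
        sys_i = CompetitionSystem(64, 50, 10.4, 200.0)
        design = ExperimentDesign(mode="competition", system=sys_i,
                                  noise_sd=0.03, n_replicates=3, seed=31)
        cmp = compare_models(generate_competition(design), sys_i)
        # the F-test must not reject the competitive (null) model
        assert cmp.p_value >= 0.05
        assert cmp.verdict != "affinity_shift"

    def test_shift_truth_favors_shift(self):
        sys_i = CompetitionSystem(64, 50, 10.4, 200.0)
        design = ExperimentDesign(mode="competition", system=sys_i,
                                  competition_model="affinity_shift", alpha=5.0,
                                  noise_sd=0.03, n_replicates=3, seed=37)
        cmp = compare_models(generate_competition(design), sys_i)
        assert cmp.verdict == "affinity_shift"
        assert cmp.p_value < 0.05
        assert cmp.aicc_shift < cmp.aicc_competitive
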