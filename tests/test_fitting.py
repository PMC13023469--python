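"""Tests for least-squares estimation, constrained schemes and metrics."""

import numpy as np
import pytest

from nerveimpedance import (
    FitConfig,
    FrequencyGrid,
    ImpedanceSpectrum,
    NoiseModel,
    ParameterError,
    compare_representations,
    constrained_fit,
    fit_spectrum,
    goodness_of_fit,
    nmse,
    rank_constrained_models,
    reference_state_parameters,
    simulate_spectrum,
    single_element_impedance,
)
from nerveimpedance.fitting import (
    SCHEME_FREE_PARAMETERS,
    ConstraintScheme,
    chi2_red_from_ssr,
    rmse_log_from_ssr,
    rmse_pct_from_ssr,
)


NOISELESS = NoiseModel(relative_sd=0.0, replicates=1)


class TestMetricFormulas:
    def test_perfect_fit(self):
        m = np.array([100.0, 50.0, 20.0, 10.0])
        g = goodness_of_fit(m, m, n_free_params=2)
        assert g.ssr_rel == 0 and g.rmse_pct == 0
        assert g.ssr_log == 0 and g.rmse_log == 0 and g.chi2_red == 0
        assert g.r2 == 1.0 and g.nmse == 0.0

    def test_nmse_hand_example(self):
        # residual 1 at the last point over SS_tot = 2
        assert nmse([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_nmse_of_mean_predictor_is_one(self):
        m = np.array([1.0, 2.0, 3.0, 10.0])
        assert nmse(m, np.full_like(m, m.mean())) == pytest.approx(1.0)

    def test_nmse_plus_r2_is_one(self):
        rng = np.random.default_rng(0)
        m = 10 ** rng.uniform(1, 5, 40)
        f = m * (1 + 0.05 * rng.standard_normal(40))
        g = goodness_of_fit(m, f, n_free_params=8)
        assert g.nmse + g.r2 == pytest.approx(1.0, abs=1e-15)
        assert g.nmse == pytest.approx(nmse(m, f), rel=1e-15)

    def test_constant_measured_rejected(self):
        with pytest.raises(ParameterError):
            nmse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_measured_rejected(self):
        with pytest.raises(ParameterError):
            goodness_of_fit([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], 1)

    def test_chi2_requires_spare_degrees_of_freedom(self):
        with pytest.raises(ParameterError):
            chi2_red_from_ssr(1.0, n=8, p=8)

    def test_suite_internal_consistency(self):
        rng = np.random.default_rng(1)
        m = 10 ** rng.uniform(1, 5, 35)
        f = m * (1 + 0.02 * rng.standard_normal(35))
        g = goodness_of_fit(m, f, n_free_params=8)
        assert g.rmse_pct == pytest.approx(rmse_pct_from_ssr(g.ssr_rel, 35))
        assert g.rmse_log == pytest.approx(rmse_log_from_ssr(g.ssr_log, 35))
        assert g.chi2_red == pytest.approx(chi2_red_from_ssr(g.ssr_log, 35, 8))


class TestSchemes:
    def test_free_parameter_subsets(self):
        assert SCHEME_FREE_PARAMETERS["free_endo"] == (
            "Rendo", "Cendo", "Cendo_peri")
        assert SCHEME_FREE_PARAMETERS["free_peri"] == (
            "Rperi", "Cperi", "Cendo_peri", "Cperi_epi")
        assert SCHEME_FREE_PARAMETERS["free_epi"] == (
            "Repi", "Cepi", "Cperi_epi")
        assert len(SCHEME_FREE_PARAMETERS["free_all"]) == 8

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ParameterError):
            ConstraintScheme.from_name("free_everything")


class TestFitSpectrum:
    def test_self_consistency_from_truth(self, state_params, sweep_grid):
        """Starting at the generating parameters, the optimum stays put."""
        truth = state_params["DEC"]
        spec = simulate_spectrum(truth, sweep_grid, NOISELESS, seed=0)
        res = fit_spectrum(spec, truth, FitConfig(seed=0, prefit=False,
                                                  multistart=1))
        assert res.metrics.rmse_pct < 0.1
        assert np.allclose(res.params.to_vector(), truth.to_vector(), rtol=0.05)

    def test_objective_equals_ssr_rel(self, state_params, sweep_grid):
        spec = simulate_spectrum(state_params["CT"], sweep_grid,
                                 NoiseModel(relative_sd=0.02), seed=5)
        res = fit_spectrum(spec, state_params["CT"],
                           FitConfig(seed=0, prefit=False, multistart=1))
        assert res.objective == pytest.approx(res.metrics.ssr_rel, rel=1e-9)

    def test_deterministic_given_seed(self, state_params, coarse_grid):
        spec = simulate_spectrum(state_params["REC"], coarse_grid,
                                 NoiseModel(relative_sd=0.02), seed=9)
        a = fit_spectrum(spec, state_params["REC"], FitConfig(seed=4))
        b = fit_spectrum(spec, state_params["REC"], FitConfig(seed=4))
        assert np.array_equal(a.params.to_vector(), b.params.to_vector())
        assert a.metrics.rmse_pct == b.metrics.rmse_pct

    def test_too_few_points_rejected(self, state_params):
        grid = FrequencyGrid.log_spaced(8)  # 8 points cannot pin 8 params
        spec = simulate_spectrum(state_params["CT"], grid, NOISELESS, seed=0)
        with pytest.raises(ParameterError):
            fit_spectrum(spec, state_params["CT"],
                         FitConfig(metric_grid_size=None, seed=0))

    def test_infeasible_explicit_bounds_rejected(self, state_params,
                                                 coarse_grid,
                                                 reference_initials):
        from nerveimpedance import bounds_from_initials
        spec = simulate_spectrum(state_params["CT"], coarse_grid, NOISELESS,
                                 seed=0)
        bounds = bounds_from_initials(state_params["CT"], decades=0.5)
        with pytest.raises(ParameterError):
            # reference initials sit far outside a tight box around CT
            fit_spectrum(spec, reference_initials,
                         FitConfig(bounds=bounds, seed=0))


class TestConstrainedFit:
    def test_fixed_parameters_bit_identical(self, state_params, sweep_grid):
        baseline = state_params["DEC"]
        spec = simulate_spectrum(state_params["REC"], sweep_grid,
                                 NoiseModel(relative_sd=0.02), seed=2)
        res = constrained_fit(spec, baseline, "free_epi", FitConfig(seed=0))
        fitted, base = res.params.to_dict(), baseline.to_dict()
        for name in ("Rendo", "Cendo", "Rperi", "Cperi", "Cendo_peri"):
            assert fitted[name] == base[name]

    def test_no_drift_on_baselines_own_spectrum(self, state_params, sweep_grid):
        baseline = state_params["DEC"]
        spec = simulate_spectrum(baseline, sweep_grid, NOISELESS, seed=0)
        res = constrained_fit(spec, baseline, "free_endo", FitConfig(seed=0))
        assert res.metrics.rmse_pct < 1e-4
        assert np.allclose(res.params.to_vector(), baseline.to_vector(),
                           rtol=1e-3)

    def test_free_all_rejected(self, state_params, sweep_grid):
        spec = simulate_spectrum(state_params["CT"], sweep_grid, NOISELESS,
                                 seed=0)
        with pytest.raises(ParameterError):
            constrained_fit(spec, state_params["CT"], "free_all")

    def test_nested_dominance(self, state_params, sweep_grid,
                              reference_initials):
        """The free fit can always do at least as well as any constrained
        scheme on the same spectrum (up to optimiser tolerance)."""
        spec = simulate_spectrum(state_params["REC"], sweep_grid,
                                 NoiseModel(relative_sd=0.02), seed=11)
        free = fit_spectrum(spec, reference_initials, FitConfig(seed=1))
        for scheme in ("free_endo", "free_peri", "free_epi"):
            constrained = constrained_fit(spec, state_params["DEC"], scheme,
                                          FitConfig(seed=1))
            assert free.metrics.ssr_rel <= constrained.metrics.ssr_rel * 1.05


class TestEpiOnlyPerturbation:
    def test_exactly_representable_only_by_free_epi(self, state_params,
                                                    sweep_grid):
        """A noiseless change confined to the epineurial subset is fit to
        machine precision by the epineurial scheme, while the other two
        schemes retain a systematic misfit floor."""
        dec = state_params["DEC"]
        rec = state_params["REC"].to_dict()
        truth = dec.replace(Repi=rec["Repi"], Cepi=rec["Cepi"],
                            Cperi_epi=rec["Cperi_epi"])
        spec = simulate_spectrum(truth, sweep_grid, NOISELESS, seed=0)
        rmse = {}
        for scheme in ("free_endo", "free_peri", "free_epi"):
            res = constrained_fit(spec, dec, scheme, FitConfig(seed=1))
            rmse[scheme] = res.metrics.rmse_pct
        assert rmse["free_epi"] < 1e-3
        assert rmse["free_epi"] < rmse["free_peri"] < rmse["free_endo"]


class TestRanking:
    def test_three_finite_sorted_rows(self, state_params, sweep_grid):
        spec = simulate_spectrum(state_params["REC"], sweep_grid,
                                 NoiseModel(relative_sd=0.02), seed=3)
        table = rank_constrained_models(spec, state_params["DEC"],
                                        FitConfig(seed=0))
        assert list(table.columns[:3]) == ["scheme", "rmse_pct", "r2"]
        assert len(table) == 3
        assert np.all(np.isfinite(table["rmse_pct"]))
        assert table["rmse_pct"].is_monotonic_increasing

    def test_unperturbed_baseline_gives_near_zero_rows(self, state_params,
                                                       sweep_grid):
        baseline = state_params["DEC"]
        spec = simulate_spectrum(baseline, sweep_grid, NOISELESS, seed=0)
        table = rank_constrained_models(spec, baseline, FitConfig(seed=0))
        assert np.all(table["rmse_pct"] < 1e-3)


class TestRepresentationComparison:
    @pytest.mark.parametrize("mode,expected_winner", [
        ("series_rs_cs", "series_rs_cs"),
        ("parallel_rp_cp", "parallel_rp_cp"),
    ])
    def test_matched_single_element_wins(self, mode, expected_winner):
        grid = FrequencyGrid.log_spaced(35)
        z = np.abs(single_element_impedance(mode, 2e3, 1e-7, grid.frequencies))
        report = compare_representations(ImpedanceSpectrum(grid, z))
        assert report.winner == expected_winner
        best = report.series if mode == "series_rs_cs" else report.parallel
        assert best.nmse < 1e-6

    def test_multilayer_spectrum_fits_neither_exactly(self, state_params,
                                                      sweep_grid):
        spec = simulate_spectrum(state_params["CT"], sweep_grid, NOISELESS,
                                 seed=0)
        report = compare_representations(spec)
        assert report.series.nmse > 1e-3
        assert report.parallel.nmse > 1e-3
        assert report.winner in ("series_rs_cs", "parallel_rp_cp")
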