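"""Rate-law evaluation, trace reduction, fitting and model discrimination."""

import numpy as np
import pytest

from nadhub import kinetics as kin
from nadhub import simulate as sim
from nadhub._fitting import DomainError, ParameterError


class TestEvaluateModel:
    @pytest.mark.parametrize("model,params,pred,expected", [
        ("hyperbolic_inhibition", {"v0": 100, "Imax": 1, "Ki": 1.0}, {"I": 1.0}, 50.0),
        ("hill_inhibition", {"v0": 100, "Imax": 1, "IC50": 2.5, "n": 2.2}, {"I": 2.5}, 50.0),
        ("hyperbolic_inhibition", {"v0": 100, "Imax": 1, "Ki": 1.0}, {"I": 2.5},
         100 * (1 - 2.5 / 3.5)),
        ("hyperbolic_activation", {"v_floor": 10, "v_ceil": 50, "Kact": 0.64},
         {"A": 0.0}, 10.0),
        ("effector_inhibition", {"B": 50, "T": 100, "K_E": 15.5}, {"E": 15.5}, 75.0),
        ("michaelis_menten", {"Vmax": 0.09, "Km": 0.2}, {"S": 0.2}, 0.045),
        ("noncompetitive_mm", {"Vmax": 0.08, "Km": 0.2, "Ki": 1.0},
         {"S": 1e9, "I": 1.0}, pytest.approx(0.04, rel=1e-6)),
    ])
    def test_closed_forms(self, model, params, pred, expected):
        assert kin.evaluate_model(model, params, pred) == pytest.approx(expected, rel=1e-9)

    def test_inhibition_returns_v0_at_zero_inhibitor(self):
        for model, params in [
            ("hyperbolic_inhibition", {"v0": 87.0, "Imax": 1, "Ki": 1.0}),
            ("hill_inhibition", {"v0": 87.0, "Imax": 1, "IC50": 2.5, "n": 2.2}),
        ]:
            assert kin.evaluate_model(model, params, {"I": 0.0}) == pytest.approx(87.0)

    def test_missing_parameter_raises(self):
        with pytest.raises(ParameterError):
            kin.evaluate_model("hyperbolic_inhibition", {"v0": 100}, {"I": 1.0})

    def test_negative_concentration_raises(self):
        with pytest.raises(DomainError):
            kin.evaluate_model("hyperbolic_inhibition",
                               {"v0": 100, "Imax": 1, "Ki": 1}, {"I": -1.0})

    def test_hill_n1_equals_hyperbola_pointwise(self):
        grid = np.linspace(0, 10, 101)
        hill = kin.evaluate_model("hill_inhibition",
                                  {"v0": 100, "Imax": 0.9, "IC50": 1.3, "n": 1.0},
                                  {"I": grid})
        hyp = kin.evaluate_model("hyperbolic_inhibition",
                                 {"v0": 100, "Imax": 0.9, "Ki": 1.3}, {"I": grid})
        np.testing.assert_allclose(hill, hyp, rtol=1e-12)

    def test_monotonicity_on_grids(self):
        grid = np.linspace(0, 20, 200)
        inh_hyp = kin.evaluate_model("hyperbolic_inhibition",
                                     {"v0": 100, "Imax": 1, "Ki": 1}, {"I": grid})
        inh_hill = kin.evaluate_model("hill_inhibition",
                                      {"v0": 100, "Imax": 1, "IC50": 2.5, "n": 2.2},
                                      {"I": grid})
        act = kin.evaluate_model("hyperbolic_activation",
                                 {"v_floor": 20, "v_ceil": 60, "Kact": 0.64},
                                 {"A": grid})
        assert np.all(np.diff(inh_hyp) <= 1e-12)
        assert np.all(np.diff(inh_hill) <= 1e-12)
        assert np.all(np.diff(act) >= -1e-12)


def _brute_force_linear_prefix(t, y, tol):
    """Independent oracle: grow the prefix while the slope is stable."""
    k = 3
    while k < len(t):
        s_prev = np.polyfit(t[:k], y[:k], 1)[0]
        s_next = np.polyfit(t[:k + 1], y[:k + 1], 1)[0]
        if abs(s_next - s_prev) / max(abs(s_prev), 1e-300) >= tol:
            break
        k += 1
    return k


class TestInitialVelocity:
    def test_exact_line_uses_all_points(self):
        t = np.arange(5.0)
        trace = kin.TimeCourse(t, 2.0 * t, "discontinuous_ppi")
        iv = kin.initial_velocity(trace)
        assert iv.rate == pytest.approx(2.0)
        assert iv.n_points == 5

    def test_coupled_assay_beer_lambert_conversion(self):
        t = np.arange(10.0)
        trace = kin.TimeCourse(t, 0.0622 * t, "coupled_A340")
        cfg = kin.AssayConfig(epsilon_NADH=6220.0, path_length=1.0)
        assert kin.initial_velocity(trace, cfg).rate == pytest.approx(1.0e-5)

    def test_plateau_truncates_linear_phase(self):
        t = np.arange(8.0)
        y = np.where(t <= 3, 2.0 * t, 6.0)  # linear for 4 points, then flat
        trace = kin.TimeCourse(t, y)
        iv = kin.initial_velocity(trace, kin.AssayConfig(linearity_tolerance=0.05))
        assert iv.n_points == 4
        assert iv.rate == pytest.approx(2.0)

    def test_matches_brute_force_prefix_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            t = np.arange(12.0)
            slope = rng.uniform(0.5, 3.0)
            y = slope * t + rng.normal(0, 0.02, t.size)
            y[8:] = y[8] + 0.1 * (t[8:] - t[8])  # late curvature
            iv = kin.initial_velocity(kin.TimeCourse(t, y),
                                      kin.AssayConfig(linearity_tolerance=0.05))
            assert iv.n_points == _brute_force_linear_prefix(t, y, 0.05)

    def test_too_few_points_raises(self):
        with pytest.raises(kin.InsufficientDataError):
            kin.TimeCourse([0, 1], [0, 1])

    def test_non_monotone_time_raises(self):
        with pytest.raises(DomainError):
            kin.TimeCourse([0, 2, 1], [0, 1, 2])


NOISE_FREE_CASES = [
    ("hyperbolic_inhibition", {"v0": 100.0, "Imax": 1.0, "Ki": 1.0},
     {"Imax": 1.0}, np.array([0, 0.25, 0.5, 1, 2, 3.5, 5, 10.0])),
    ("hill_inhibition", {"v0": 100.0, "Imax": 1.0, "IC50": 2.5, "n": 2.2},
     {"Imax": 1.0}, np.array([0, 0.25, 0.5, 1, 2, 3.5, 5, 10.0])),
    ("hyperbolic_activation", {"v_floor": 28.6, "v_ceil": 50.0, "Kact": 0.64},
     None, np.array([0, 0.25, 1, 2, 4, 10.0])),
    ("effector_inhibition", {"B": 50.0, "T": 100.0, "K_E": 15.5},
     None, np.array([0, 15, 30, 60, 120, 240, 360, 480.0])),
]


class TestFitting:
    @pytest.mark.parametrize("model,truth,fixed,conc", NOISE_FREE_CASES,
                             ids=[c[0] for c in NOISE_FREE_CASES])
    def test_noise_free_recovery(self, model, truth, fixed, conc):
        ds, _ = sim.gen_dose_response(model, truth, conc, noise_cv=0.0,
                                      replicates=1, seed=0)
        fit = kin.DoseResponseModel(ds, model=model, fixed=fixed).fit(seed=0)
        assert fit.converged
        for name, val in truth.items():
            assert fit.estimates[name] == pytest.approx(val, rel=1e-6)

    def test_noise_free_saturation_recovery(self):
        S = np.array([0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.4, 2.0])
        v = kin.evaluate_model("michaelis_menten", {"Vmax": 0.09, "Km": 0.2},
                               {"S": S})
        fit = kin.SaturationModel(S, v).fit(seed=0)
        assert fit.estimates["Vmax"] == pytest.approx(0.09, rel=1e-6)
        assert fit.estimates["Km"] == pytest.approx(0.2, rel=1e-6)

    def test_hill_n1_fit_matches_hyperbola_rss(self):
        conc = np.array([0, 0.25, 0.5, 1, 2, 3.5, 5, 10.0])
        ds, _ = sim.gen_dose_response("hyperbolic_inhibition",
                                      {"v0": 100, "Imax": 1, "Ki": 1.0},
                                      conc, noise_cv=0.0, replicates=1, seed=0)
        hyp = kin.DoseResponseModel(ds, "hyperbolic_inhibition").fit(seed=0)
        hill = kin.DoseResponseModel(ds, "hill_inhibition").fit(seed=0)
        assert abs(hyp.rss - hill.rss) < 1e-8

    def test_fit_is_bit_reproducible(self):
        ds, _ = sim.gen_dose_response("hill_inhibition",
                                      {"v0": 100, "Imax": 1, "IC50": 2.5, "n": 2.2},
                                      [0, 0.5, 1, 2, 3.5, 5, 10], noise_cv=0.03,
                                      seed=5)
        f1 = kin.DoseResponseModel(ds, "hill_inhibition").fit(n_starts=10, seed=3)
        f2 = kin.DoseResponseModel(ds, "hill_inhibition").fit(n_starts=10, seed=3)
        assert f1.estimates == f2.estimates
        assert f1.rss == f2.rss

    def test_seeded_noisy_recovery_within_15_percent(self):
        ds, _ = sim.gen_dose_response("hyperbolic_inhibition",
                                      {"v0": 100, "Imax": 1, "Ki": 1.0},
                                      [0, 0.25, 0.5, 1, 2, 3.5, 5, 10],
                                      noise_cv=0.03, replicates=3, seed=123)
        fit = kin.DoseResponseModel(ds).fit(seed=123)
        assert fit.estimates["Ki"] == pytest.approx(1.0, rel=0.15)

    def test_too_few_concentrations_raises(self):
        ds = kin.DoseResponseDataset([0.0, 1.0], [100.0, 50.0])
        with pytest.raises(kin.InsufficientDataError):
            kin.DoseResponseModel(ds, "hill_inhibition", fixed={})


class TestModelComparison:
    def _fits(self, source_model, truth, noise, seed):
        conc = [0, 0.25, 0.5, 1, 2, 3.5, 5, 10]
        ds, _ = sim.gen_dose_response(source_model, truth, conc,
                                      noise_cv=noise, replicates=3, seed=seed)
        hyp = kin.DoseResponseModel(ds, "hyperbolic_inhibition").fit(seed=seed)
        hill = kin.DoseResponseModel(ds, "hill_inhibition").fit(seed=seed)
        return hyp, hill

    def test_identical_fits_no_preference(self):
        hyp, _ = self._fits("hyperbolic_inhibition",
                            {"v0": 100, "Imax": 1, "Ki": 1.0}, 0.0, 0)
        rep = kin.compare_models(hyp, hyp, "f_test")
        assert rep.preferred is None
        assert rep.statistic == 0.0

    def test_cooperative_data_prefers_hill(self):
        hyp, hill = self._fits("hill_inhibition",
                               {"v0": 100, "Imax": 1, "IC50": 2.5, "n": 2.2},
                               0.02, 11)
        rep = kin.compare_models(hyp, hill, "f_test", alpha=0.05)
        assert rep.preferred == "hill_inhibition"

    def test_hyperbolic_data_prefers_hyperbola_by_aicc(self):
        hyp, hill = self._fits("hyperbolic_inhibition",
                               {"v0": 100, "Imax": 1, "Ki": 1.0}, 0.02, 11)
        rep = kin.compare_models(hyp, hill, "aicc")
        assert rep.preferred == "hyperbolic_inhibition"

    def test_different_datasets_rejected(self):
        hyp, _ = self._fits("hyperbolic_inhibition",
                            {"v0": 100, "Imax": 1, "Ki": 1.0}, 0.0, 0)
        other = kin.FitResult("m", {}, {}, 0.0, hyp.n_obs + 1, True, 0, 1)
        with pytest.raises(ValueError):
            kin.compare_models(hyp, other)


class TestClassifyInhibition:
    S = np.repeat(np.array([0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.4, 2.0]), 3)

    def _fit(self, Vmax, Km, seed, cv=0.02):
        rng = np.random.default_rng(seed)
        v = kin.evaluate_model("michaelis_menten", {"Vmax": Vmax, "Km": Km},
                               {"S": self.S})
        v = v * (1 + rng.normal(0, cv, v.size))
        return kin.SaturationModel(self.S, v).fit(seed=seed)

    def test_vmax_drop_with_constant_km_is_allosteric(self):
        # mirrors the NAD+ effect: Vmax 0.09 -> 0.04 umol/s, Km untouched
        label, _ = kin.classify_inhibition(self._fit(0.09, 0.2, 1),
                                           self._fit(0.04, 0.2, 2))
        assert label == "noncompetitive_allosteric"

    def test_identical_fits_indeterminate(self):
        fit = self._fit(0.09, 0.2, 3)
        label, _ = kin.classify_inhibition(fit, fit)
        assert label == "indeterminate"

    def test_km_shift_with_constant_vmax_is_competitive(self):
        label, _ = kin.classify_inhibition(self._fit(0.09, 0.2, 4),
                                           self._fit(0.09, 0.4, 5))
        assert label == "competitive"
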