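import numpy as np
import pytest
from scipy import stats

from aqbd.desirability import overlay
from aqbd.robustness import (
    RobustnessConfig,
    SpecLimits,
    capability,
    check_verification_runs,
    monte_carlo_modr,
    verify_par,
)


class TestCapability:
    def test_cp_eight_sigma_width(self):
        lim = SpecLimits("r", lsl=-4.0, usl=4.0)
        assert capability(0.0, 1.0, lim, "Cp") == pytest.approx(8 / 6)

    def test_cp_one_means_997_coverage(self):
        lim = SpecLimits("r", lsl=-3.0, usl=3.0)
        assert capability(0.0, 1.0, lim, "Cp") == pytest.approx(1.0)
        coverage = stats.norm.cdf(3) - stats.norm.cdf(-3)
        assert coverage == pytest.approx(0.997, abs=5e-4)

    def test_mean_on_lsl_gives_zero(self):
        lim = SpecLimits("r", lsl=2.0)
        assert capability(2.0, 0.5, lim, "Cpk") == 0.0

    def test_cpk_le_cp_equality_iff_centered(self):
        lim = SpecLimits("r", lsl=0.0, usl=10.0)
        for mean in (5.0, 6.0, 9.0):
            cp = capability(mean, 1.0, lim, "Cp")
            cpk = capability(mean, 1.0, lim, "Cpk")
            assert cpk <= cp + 1e-12
            if mean == 5.0:
                assert cpk == pytest.approx(cp)

    def test_taguchi_indices(self):
        lim = SpecLimits("r", lsl=0.0, usl=10.0, target=5.0)
        assert capability(5.0, 1.0, lim, "Cpm") == pytest.approx(10 / 6)
        off = capability(6.0, 1.0, lim, "Cpm")
        assert off == pytest.approx(10 / (6 * np.sqrt(2)))
        cpk = capability(6.0, 1.0, lim, "Cpk")
        assert capability(6.0, 1.0, lim, "Cpkm") == pytest.approx(cpk / np.sqrt(2))

    def test_degenerate_and_invalid(self):
        lim = SpecLimits("r", lsl=0.0, usl=10.0)
        assert capability(5.0, 0.0, lim, "Cpk") == np.inf
        assert capability(-1.0, 0.0, lim, "Cpk") == -np.inf
        with pytest.raises(ValueError):
            capability(5.0, 1.0, SpecLimits("r", lsl=0.0), "Cp")
        with pytest.raises(ValueError):
            capability(5.0, 1.0, lim, "Cpm")  # no target
        with pytest.raises(ValueError):
            SpecLimits("r")


@pytest.fixture(scope="module")
def fixture_limits(fx):
    return [
        SpecLimits(name, lsl=d.get("lower"), usl=d.get("upper"))
        for name, d in fx.limits.items()
    ]


class TestMonteCarloMODR:
    def test_zero_sigma_no_noise_equals_mean_overlay(self, fx, fixture_limits):
        cfg = RobustnessConfig(factor_variations={"A": 0.0, "B": 0.0, "C": 0.0},
                               n_sims=200, seed=1, response_noise=False)
        modr = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"),
                                resolution=13)
        ov = overlay(fx.models, fx.limits, ("B", "C"), resolution=13)
        np.testing.assert_array_equal(modr.pass_grid, ov.pass_all)

    def test_modr_subset_of_mean_overlay(self, fx, fixture_limits):
        cfg = RobustnessConfig(factor_variations=fx.factor_variations,
                               n_sims=1500, seed=2, response_noise=False)
        modr = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"),
                                resolution=13)
        ov = overlay(fx.models, fx.limits, ("B", "C"), resolution=13)
        assert np.all(~modr.pass_grid | ov.pass_all)
        assert modr.pass_grid.sum() < ov.pass_all.sum()

    def test_seed_determinism_bit_identical(self, fx, fixture_limits):
        cfg = RobustnessConfig(factor_variations=fx.factor_variations,
                               n_sims=500, seed=11)
        a = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"), resolution=7)
        b = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"), resolution=7)
        np.testing.assert_array_equal(a.pass_grid, b.pass_grid)
        for name in a.capability_values:
            np.testing.assert_array_equal(a.capability_values[name],
                                          b.capability_values[name])

    def test_threshold_monotonicity(self, fx, fixture_limits):
        passes = []
        for thr in (1.0, 1.33, 2.0):
            cfg = RobustnessConfig(factor_variations=fx.factor_variations,
                                   threshold=thr, n_sims=800, seed=3)
            modr = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"),
                                    resolution=9)
            passes.append(modr.pass_grid)
        assert np.all(passes[1] <= passes[0])
        assert np.all(passes[2] <= passes[1])

    def test_sigma_monotonicity_common_random_numbers(self, fx, fixture_limits):
        passes = []
        for scale in (0.5, 1.0, 2.0):
            cfg = RobustnessConfig(
                factor_variations={k: v * scale for k, v in fx.factor_variations.items()},
                n_sims=800, seed=4, response_noise=False,
            )
            modr = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"),
                                    resolution=9)
            passes.append(modr.pass_grid)
        assert np.all(passes[1] <= passes[0])
        assert np.all(passes[2] <= passes[1])

    def test_linear_model_cpk_matches_closed_form(self, two_factor_linear):
        """Simulated Cpk at a fixed point converges to the value obtained by
        exact normal propagation through the linear map."""
        d, fit, _ = two_factor_linear
        lim = SpecLimits("y", lsl=3.0)
        sds_actual = {"X": 0.05, "Y": 0.8}
        n_sims = 100_000
        cfg = RobustnessConfig(factor_variations={k: 3 * v for k, v in sds_actual.items()},
                               n_sims=n_sims, seed=9, response_noise=False)
        modr = monte_carlo_modr({"y": fit}, [lim], cfg, ("X", "Y"), resolution=3)
        # closed form at each grid point: y ~ N(b0 + b1 x1 + b2 x2, sum (b_i sigma_i^coded)^2)
        sig_coded = cfg.sigma_coded(d.factors)
        sd_y = np.sqrt(np.sum((fit.b[1:] * sig_coded) ** 2))
        for i, g1 in enumerate(modr.axis_coded[0]):
            for j, g2 in enumerate(modr.axis_coded[1]):
                mean_y = float(fit.b @ [1.0, g1, g2])
                cpk_true = (mean_y - lim.lsl) / (3 * sd_y)
                cpk_sim = modr.capability_values["y"][i, j]
                se = np.sqrt(1 / (9 * n_sims) + cpk_true**2 / (2 * n_sims))
                assert abs(cpk_sim - cpk_true) < 3 * se

    def test_extrapolation_fraction_recorded(self, fx, fixture_limits):
        cfg = RobustnessConfig(factor_variations={"A": 0.3, "B": 15.0, "C": 15.0},
                               n_sims=500, seed=5)
        modr = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"),
                                resolution=5)
        assert modr.extrapolation_fraction.max() > 0.01
        assert modr.warnings


class TestVerifyPar:
    def test_rectangle_inside_pass_region(self, fx, fixture_limits):
        cfg = RobustnessConfig(factor_variations={"A": 0.0, "B": 0.0, "C": 0.0},
                               n_sims=200, seed=1, response_noise=False)
        modr = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"),
                                resolution=21, slice_coded={"A": 0.125})
        # a small rectangle around the verification point's (B, C)
        verdict = verify_par(modr, {"B": (53.0, 57.0), "C": (33.0, 38.0)})
        assert verdict.passed
        assert verdict.n_inside > 0

    def test_failing_rectangle_lists_coordinates(self, fx, fixture_limits):
        cfg = RobustnessConfig(factor_variations={"A": 0.0, "B": 0.0, "C": 0.0},
                               n_sims=200, seed=1, response_noise=False)
        modr = monte_carlo_modr(fx.models, fixture_limits, cfg, ("B", "C"),
                                resolution=21)
        verdict = verify_par(modr, {"B": (50.0, 70.0), "C": (25.0, 50.0)})
        assert not verdict.passed
        assert len(verdict.failing_points) > 0
        with pytest.raises(ValueError):
            verify_par(modr, {"B": (80.0, 90.0), "C": (25.0, 50.0)})

    def test_verification_point_T_is_robust(self, fx, fixture_limits):
        """Point T passes Cpk >= 1.33 for all eight responses under the
        study's input variations."""
        T_coded = np.array([0.125, -0.5, -0.2])
        rng = np.random.default_rng(123)
        cfg = RobustnessConfig(factor_variations=fx.factor_variations,
                               n_sims=20_000, seed=123, response_noise=False)
        sig = cfg.sigma_coded(fx.factors)
        draws = T_coded + rng.standard_normal((cfg.n_sims, 3)) * sig
        for lim in fixture_limits:
            y = fx.models[lim.response_name].predict_coded(draws)
            cpk = capability(float(y.mean()), float(y.std(ddof=1)), lim, "Cpk")
            assert cpk >= 1.33, lim.response_name


class TestVerificationRuns:
    def test_reported_verification_runs_within_bounds(self, fx):
        predicted = {n: (v[1], v[2], v[3]) for n, v in fx.table7.items()}
        experimental = {n: v[0] for n, v in fx.table7.items()}
        table = check_verification_runs(predicted, experimental)
        assert table["within"].all()

    def test_boundary_is_closed_and_outside_detected(self):
        pred = {"a": (3.6, 3.38, 3.90), "b": (3.6, 3.38, 3.90)}
        exp = {"a": 3.90, "b": 5.0}
        table = check_verification_runs(pred, exp).set_index("response")
        assert bool(table.loc["a", "within"])
        assert not bool(table.loc["b", "within"])
        with pytest.raises(ValueError):
            check_verification_runs(pred, {"a": 1.0})


class TestModelChoicePropagation:
    def test_borderline_term_choice_changes_modr_map(self, fx, design19):
        """Keeping vs. dropping a borderline model term (the effect of
        raising the F-to-remove threshold) changes the downstream MODR."""
        from aqbd.fixtures import SyntheticSpec, generate_responses
        from aqbd.model import fit_model

        truth = fx.models["k BMC"]
        tab = generate_responses(SyntheticSpec(design19, {"y": truth}, 0.104, seed=13))
        y = tab["y"].to_numpy()
        with_extra = fit_model(design19, y, truth.spec.add(("A", "C")))
        without = fit_model(design19, y, truth.spec)
        for f_ in (with_extra, without):
            f_.factors = fx.factors
        lim = [SpecLimits("y", lsl=2.0)]
        cfg = RobustnessConfig(factor_variations=fx.factor_variations,
                               n_sims=2000, seed=13, response_noise=False)
        m1 = monte_carlo_modr({"y": with_extra}, lim, cfg, ("B", "C"), resolution=31)
        m2 = monte_carlo_modr({"y": without}, lim, cfg, ("B", "C"), resolution=31)
        assert not np.array_equal(m1.capability_values["y"], m2.capability_values["y"])
        # the Cpk surfaces differ materially, not just in the last digits
        assert np.max(np.abs(m1.capability_values["y"] - m2.capability_values["y"])) > 0.01
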