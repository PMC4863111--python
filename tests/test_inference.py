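from dataclasses import replace

import numpy as np
import pytest

from glucolag import (
    FitResult,
    GlucoseTimeSeries,
    GTTProfileParams,
    InvalidInputError,
    ModelConfig,
    NoFeatureError,
    TissueParams,
    estimate_lag,
    fit_diffusion_distance,
    relative_errors,
    simulate_isf,
)


@pytest.fixture
def scenario_config() -> ModelConfig:
    return replace(ModelConfig(), tissue=TissueParams(264.0, 24.0, 100.0))


class TestRelativeErrors:
    def test_identical(self):
        s = GlucoseTimeSeries([0.0, 10.0], [100.0, 200.0])
        assert relative_errors(s, s) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        # errors [10/100, 20/200] = [0.10, 0.10]
        m = GlucoseTimeSeries([0.0, 10.0], [100.0, 200.0])
        p = GlucoseTimeSeries([0.0, 10.0], [110.0, 180.0])
        assert relative_errors(m, p) == pytest.approx((0.10, 0.10))

    def test_hand_arithmetic_asymmetric(self):
        # errors [10/100, 10/200] = [0.10, 0.05] -> (0.10, 0.075)
        m = GlucoseTimeSeries([0.0, 10.0], [100.0, 200.0])
        p = GlucoseTimeSeries([0.0, 10.0], [110.0, 190.0])
        assert relative_errors(m, p) == pytest.approx((0.10, 0.075))

    def test_uniform_scaling(self):
        m = GlucoseTimeSeries([0.0, 5.0, 10.0], [90.0, 150.0, 120.0])
        p = m.with_values(1.2 * m.values)
        mx, mean = relative_errors(m, p)
        assert mx == pytest.approx(0.20)
        assert mean == pytest.approx(0.20)

    def test_scale_invariance(self):
        m = GlucoseTimeSeries([0.0, 5.0, 10.0], [90.0, 150.0, 120.0])
        p = GlucoseTimeSeries([0.0, 5.0, 10.0], [100.0, 140.0, 119.0])
        base = relative_errors(m, p)
        scaled = relative_errors(m.with_values(3.5 * m.values),
                                 p.with_values(3.5 * p.values))
        assert scaled == pytest.approx(base)

    def test_zero_measured_rejected(self):
        m = GlucoseTimeSeries([0.0, 10.0], [0.0, 200.0])
        p = GlucoseTimeSeries([0.0, 10.0], [10.0, 180.0])
        with pytest.raises(InvalidInputError):
            relative_errors(m, p)

    def test_grid_mismatch_rejected(self):
        m = GlucoseTimeSeries([0.0, 10.0], [100.0, 200.0])
        p = GlucoseTimeSeries([0.0, 11.0], [100.0, 200.0])
        with pytest.raises(InvalidInputError):
            relative_errors(m, p)


class TestEstimateLag:
    def test_exact_shift_recovery(self, gtt_blood):
        shifted = GlucoseTimeSeries(gtt_blood.times + 3.0, gtt_blood.values)
        assert estimate_lag(gtt_blood, shifted) == pytest.approx(3.0, abs=0.051)

    def test_coincident_peaks(self, gtt_blood):
        assert estimate_lag(gtt_blood, gtt_blood, method="peak") == 0.0

    def test_peak_method_floors_at_zero(self):
        t = np.arange(0.0, 50.1, 1.0)
        blood = GlucoseTimeSeries(t, np.exp(-0.5 * ((t - 30) / 5.0) ** 2) * 100 + 100)
        early = GlucoseTimeSeries(t, np.exp(-0.5 * ((t - 20) / 5.0) ** 2) * 100 + 100)
        assert estimate_lag(blood, early, method="peak") == 0.0

    def test_constant_series_rejected(self, gtt_blood):
        flat = gtt_blood.with_values(np.full(len(gtt_blood), 100.0))
        with pytest.raises(NoFeatureError):
            estimate_lag(gtt_blood, flat)
        with pytest.raises(NoFeatureError):
            estimate_lag(flat, gtt_blood, method="peak")

    def test_shift_equivariance(self, gtt_blood, scenario_config):
        isf = simulate_isf(gtt_blood, scenario_config)
        base = estimate_lag(gtt_blood, isf)
        for delta in (2.0, 5.0):
            moved = GlucoseTimeSeries(isf.times + delta, isf.values)
            est = estimate_lag(gtt_blood, moved, max_lag=40.0)
            assert est == pytest.approx(base + delta, abs=0.11)

    def test_rat_like_peak_lag_regime(self):
        """With the step half-rise near 2.4 min at 24 um, the peak delay on
        a GTT pulse sampled every 10 min falls in the 5-15 min range."""
        gtt = GTTProfileParams()
        t = np.arange(5.0, 120.1, 10.0)
        blood = GlucoseTimeSeries(t, gtt.evaluate(t))
        cfg = replace(ModelConfig(), tissue=TissueParams(264.0, 24.0, gtt.baseline))
        isf = simulate_isf(blood, cfg)
        lag = estimate_lag(blood, isf, method="peak")
        assert 5.0 <= lag <= 15.0

    def test_unknown_method_rejected(self, gtt_blood):
        with pytest.raises(InvalidInputError):
            estimate_lag(gtt_blood, gtt_blood, method="wavelet")


class TestFitDiffusionDistance:
    def test_self_consistency_noise_free(self, gtt_blood, scenario_config):
        truth = simulate_isf(gtt_blood, scenario_config)
        res = fit_diffusion_distance(gtt_blood, truth, scenario_config)
        assert res.x_best_um == 24.0
        assert res.mean_rel_error < 1e-9
        assert res.max_rel_error < 1e-9

    def test_recovers_every_grid_member(self, gtt_blood, scenario_config):
        for x_true in (18.0, 24.0, 30.0):
            truth = simulate_isf(gtt_blood, scenario_config.with_x(x_true))
            res = fit_diffusion_distance(gtt_blood, truth, scenario_config)
            assert res.x_best_um == x_true

    def test_winner_has_minimal_mean_error(self, gtt_blood, scenario_config):
        rng = np.random.default_rng(11)
        truth = simulate_isf(gtt_blood, scenario_config)
        noisy = truth.with_values(truth.values * rng.lognormal(0, 0.05, len(truth)))
        res = fit_diffusion_distance(gtt_blood, noisy, scenario_config)
        best_mean = res.error_table[res.x_best_um][1]
        assert all(best_mean <= mean for _, mean in res.error_table.values())
        assert res.mean_rel_error == best_mean

    def test_noisy_recovery_montecarlo(self, gtt_blood, scenario_config):
        """5% multiplicative noise on a densely sampled trace: the
        generating distance wins in >= 90% of replicates."""
        truth = simulate_isf(gtt_blood, scenario_config)
        wins = 0
        n = 30
        for seed in range(n):
            rng = np.random.default_rng(seed)
            noisy = truth.with_values(
                truth.values * rng.lognormal(-0.00125, 0.05, len(truth))
            )
            res = fit_diffusion_distance(gtt_blood, noisy, scenario_config)
            wins += res.x_best_um == 24.0
        assert wins >= 0.9 * n

    def test_empty_grid_rejected(self, gtt_blood, scenario_config):
        with pytest.raises(InvalidInputError):
            fit_diffusion_distance(gtt_blood, gtt_blood, scenario_config, grid=())

    def test_refine_stays_in_range(self, gtt_blood, scenario_config):
        truth = simulate_isf(gtt_blood, scenario_config)
        res = fit_diffusion_distance(gtt_blood, truth, scenario_config, refine=True)
        assert 18.0 <= res.x_refined_um <= 30.0
        assert res.x_refined_um == pytest.approx(24.0, abs=0.5)

    def test_rmse_objective(self, gtt_blood, scenario_config):
        truth = simulate_isf(gtt_blood, scenario_config)
        res = fit_diffusion_distance(
            gtt_blood, truth, scenario_config, objective="rmse"
        )
        assert res.x_best_um == 24.0

    def test_fit_result_invariants(self):
        with pytest.raises(InvalidInputError):
            FitResult(x_best_um=20.0, grid_um=(18.0, 24.0), lag_min=1.0,
                      max_rel_error=0.1, mean_rel_error=0.05)
        with pytest.raises(InvalidInputError):
            FitResult(x_best_um=18.0, grid_um=(18.0,), lag_min=-1.0,
                      max_rel_error=0.1, mean_rel_error=0.05)
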