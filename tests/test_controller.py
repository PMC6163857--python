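"""Controller core: growth-rate estimation, forecast/required-biomass
inverse pair, dilution-factor arithmetic, volume planning against a
brute-force oracle, harvest rule, cycle-time adaptation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from platestat import (
    ControllerConfig,
    adapt_cycle_time,
    compute_dilution_factor,
    estimate_growth_rate,
    harvest_ready,
    plan_dilution_volumes,
    predict_biomass,
    required_biomass,
)


class TestGrowthRateEstimate:
    @pytest.mark.parametrize(
        "x0, x1, t0, t1, expected",
        [
            (0.2, 0.4, 0.0, 1.0, math.log(2)),
            (0.3, 0.3, 0.0, 1.0, 0.0),
            (0.1, 0.8, 0.0, 3.0, math.log(8) / 3),
        ],
    )
    def test_log_ratio(self, x0, x1, t0, t1, expected):
        assert estimate_growth_rate(x0, x1, t0, t1) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize(
        "args", [(0.0, 0.4, 0, 1), (0.2, -0.1, 0, 1), (0.2, 0.4, 1, 1)]
    )
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            estimate_growth_rate(*args)


class TestForecastPair:
    def test_reference_strain_forecast(self):
        """One-cycle forecast from the printed OD 0.44 and mu 1.32 h^-1 of
        the fastest reference strain rounds to 1.65."""
        assert round(predict_biomass(0.44, 1.32, 1.0), 2) == 1.65

    def test_zero_mu_is_identity(self):
        assert predict_biomass(0.5, 0.0, 1.0) == 0.5
        assert required_biomass(0.8, 0.0, 1.0) == 0.8

    def test_required_biomass_value(self):
        assert required_biomass(0.8, 1.32, 1.0) == pytest.approx(
            0.8 / math.exp(1.32), rel=1e-12
        )

    @given(
        mu=st.floats(0.0, 3.0),
        dt=st.floats(0.25, 2.0),
        x=st.floats(0.1, 2.0),
    )
    def test_exact_inverse(self, mu, dt, x):
        assert predict_biomass(required_biomass(x, mu, dt), mu, dt) == pytest.approx(
            x, abs=1e-12
        )


class TestDilutionFactor:
    def test_ratio(self):
        assert compute_dilution_factor(0.2137, 0.44) == pytest.approx(
            0.2137 / 0.44, rel=1e-12
        )

    @pytest.mark.parametrize("req, meas", [(0.8, 0.4), (0.4, 0.4)])
    def test_no_dilution_at_factor_ge_one(self, req, meas):
        assert compute_dilution_factor(req, meas) is None

    def test_nonpositive_measured_rejected(self):
        with pytest.raises(ValueError):
            compute_dilution_factor(0.5, 0.0)


def brute_force_plan(f: float, cfg: ControllerConfig) -> float:
    """Independent oracle: enumerate every integer removal volume and pick
    the one whose achieved factor is closest to the request (ties to the
    smaller removal)."""
    V, s = cfg.culture_volume, cfg.sample_vol
    r_candidates = np.arange(0, V - s - cfg.min_residual_vol + 1e-9, 1.0)
    errs = np.abs((V - s - r_candidates) / V - f)
    return float(r_candidates[int(np.argmin(errs))])  # argmin takes first=smallest


class TestPlanDilutionVolumes:
    def test_worked_example(self):
        cfg = ControllerConfig()
        plan = plan_dilution_volumes(0.4857, cfg)
        assert plan.remove_vol == 67.0
        assert plan.add_medium_vol == 87.0
        assert plan.factor_achieved == pytest.approx(83 / 170, rel=1e-12)
        assert not plan.clamped

    def test_no_dilution_replaces_sample_only(self):
        plan = plan_dilution_volumes(None, ControllerConfig())
        assert plan.remove_vol == 0.0
        assert plan.add_medium_vol == 20.0
        assert plan.factor_requested is None
        assert plan.factor_achieved == 1.0

    def test_infeasibly_strong_dilution_clamped(self):
        plan = plan_dilution_volumes(0.03, ControllerConfig())
        assert plan.clamped
        assert plan.remove_vol == 140.0
        assert plan.add_medium_vol == 160.0
        assert plan.factor_achieved == pytest.approx(10 / 170, rel=1e-12)

    def test_volume_conservation(self):
        for f in (None, 0.2, 0.5, 0.9, 0.99):
            plan = plan_dilution_volumes(f, ControllerConfig())
            assert plan.add_medium_vol == plan.remove_vol + 20.0

    def test_matches_brute_force_oracle(self):
        """1,000 random (factor, config) instances agree with exhaustive
        integer-volume search."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            V = float(rng.integers(100, 301))
            s = float(rng.integers(5, 41))
            mr = float(rng.integers(5, 31))
            cfg = ControllerConfig(
                culture_volume=V,
                sample_vol=s,
                min_residual_vol=mr,
                pipette_resolution=1.0,
            )
            f = float(rng.uniform(0.01, 0.999))
            plan = plan_dilution_volumes(f, cfg)
            assert plan.remove_vol == brute_force_plan(f, cfg), (f, cfg)

    def test_achieved_factor_monotone_in_request(self):
        cfg = ControllerConfig()
        fs = np.linspace(10 / 170, 150 / 170, 400)
        achieved = [plan_dilution_volumes(float(f), cfg).factor_achieved for f in fs]
        assert all(b - a >= 0 for a, b in zip(achieved, achieved[1:]))

    @given(
        mu=st.floats(0.0, 3.0),
        x_meas=st.floats(0.3, 1.5),
    )
    def test_one_step_deadbeat_up_to_quantization(self, mu, x_meas):
        """With a perfect mu estimate, diluting per plan and growing one
        cycle lands on the setpoint up to the volume-quantization error
        (half a pipette step on the factor, amplified by one cycle of
        growth)."""
        cfg = ControllerConfig()
        growth = math.exp(mu * cfg.cycle_time)
        f = compute_dilution_factor(
            required_biomass(cfg.x_threshold, mu, cfg.cycle_time), x_meas
        )
        if f is None or f < cfg.min_residual_vol / cfg.culture_volume:
            return  # outside the regulable band
        plan = plan_dilution_volumes(f, cfg)
        if plan.clamped:
            return
        landed = x_meas * plan.factor_achieved * growth
        bound = 0.5 * cfg.pipette_resolution / cfg.culture_volume * x_meas * growth
        assert abs(landed - cfg.x_threshold) <= bound + 1e-12
        if mu * cfg.cycle_time <= math.log(2):
            # slow growers meet the tighter linear bound
            assert (
                abs(landed - cfg.x_threshold)
                <= cfg.pipette_resolution / cfg.culture_volume * x_meas + 1e-12
            )

    def test_continuous_resolution_is_exact(self):
        cfg = ControllerConfig(pipette_resolution=0.0)
        f = 0.31415
        plan = plan_dilution_volumes(f, cfg)
        assert plan.factor_achieved == pytest.approx(f, abs=1e-12)


class TestHarvestReady:
    def test_reference_final_cycle_harvests(self):
        assert harvest_ready([0.80, 0.79, 0.78], ControllerConfig())

    def test_reference_third_cycle_continues(self):
        assert not harvest_ready([0.76, 0.68, 0.56], ControllerConfig())

    def test_single_well_on_setpoint(self):
        assert harvest_ready([0.8], ControllerConfig(harvest_tol=0.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            harvest_ready([], ControllerConfig())


class TestAdaptCycleTime:
    @pytest.mark.parametrize(
        "mus, expected",
        [
            ([math.log(2)], 2.0),  # ln4/ln2 = 2, at the upper clamp
            ([1.3863], 1.0),
            ([2.7726], 0.5),
        ],
    )
    def test_fold_growth_rule(self, mus, expected):
        assert adapt_cycle_time(mus, ControllerConfig()) == pytest.approx(
            expected, rel=1e-3
        )

    def test_slow_wells_raise_cycle_time_for_sustainability(self):
        # mu = 0.1 h^-1 needs T >= ln(170/150)/0.1 = 1.25 h to survive sampling
        T = adapt_cycle_time([0.1, 2.7726], ControllerConfig())
        assert T == pytest.approx(math.log(170 / 150) / 0.1, rel=1e-9)

    def test_no_positive_estimate_keeps_current_and_warns(self):
        cfg = ControllerConfig(cycle_time=1.0)
        with pytest.warns(UserWarning):
            assert adapt_cycle_time([-0.2, 0.0], cfg) == 1.0
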