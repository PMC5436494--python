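"""Flow program: thermal expansion, ramp velocity, residence-time
transform and the injection schedule."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import rampkin as rk
from rampkin.errors import ConfigError, ScheduleError
from rampkin.flow import ML_MIN_TO_M3_S


def make_ramp(Q0=10.0, Q_end=1.5, alpha=0.836, hold=2.0, T_C=25.0):
    return rk.RampProgram(
        pump_flows_start={"P1": 0.25 * Q0, "P2": 0.55 * Q0, "P3": 0.2 * Q0},
        Q_end=Q_end, alpha=alpha, hold_min=hold, temperature_C=T_C,
    )


def tau_numeric(geom, ramp, beta, t_exit_s):
    """Independent oracle: invert the swept-volume integral
    beta * int_{t-tau}^t Q dt' = V by bisection on tau."""
    from helpers_flow import tau_numeric_oracle

    return tau_numeric_oracle(geom, ramp, t_exit_s, beta=beta)


class TestThermalExpansion:
    def test_unity_at_ambient(self):
        m = rk.ThermalExpansionModel()
        assert rk.thermal_expansion_factor(m, m.T0) == 1.0

    def test_scalar_value(self):
        m = rk.ThermalExpansionModel(alpha_v=1.1e-3, T0=298.15)
        assert rk.thermal_expansion_factor(m, 393.15) == pytest.approx(1.1045)

    def test_zero_coefficient(self):
        m = rk.ThermalExpansionModel(alpha_v=0.0)
        for T in (250.0, 300.0, 400.0):
            assert rk.thermal_expansion_factor(m, T) == 1.0


class TestVelocity:
    def test_start_velocity(self, geometry, no_expansion):
        # 10 mL/min through a 0.79 mm tube ~ 0.340 m/s
        ramp = make_ramp()
        u = rk.velocity_at_time(geometry, ramp, no_expansion, 298.15, 0.0)
        expected = (10.0 * ML_MIN_TO_M3_S) / (math.pi * (0.395e-3) ** 2)
        assert u == pytest.approx(expected, rel=1e-12)
        assert u == pytest.approx(0.340, abs=0.001)

    def test_constant_when_alpha_zero(self, geometry, no_expansion):
        ramp = make_ramp(alpha=0.0)
        us = [rk.velocity_at_time(geometry, ramp, no_expansion, 298.15, t)
              for t in (0.0, 60.0, 600.0)]
        assert len(set(us)) == 1

    def test_linear_in_beta(self, geometry):
        ramp = make_ramp()
        m1 = rk.ThermalExpansionModel(alpha_v=0.0)
        m2 = rk.ThermalExpansionModel(alpha_v=1.0 / 95.0, T0=298.15)  # beta = 2
        u1 = rk.velocity_at_time(geometry, ramp, m1, 393.15, 30.0)
        u2 = rk.velocity_at_time(geometry, ramp, m2, 393.15, 30.0)
        assert u2 == pytest.approx(2 * u1, rel=1e-12)


class TestResidenceTime:
    def test_steady_flow_is_volume_over_flow(self, geometry, no_expansion):
        # 5 mL at 10 mL/min -> 0.5 min, exactly
        ramp = make_ramp(alpha=0.0)
        tau = rk.residence_time_of_sample(geometry, ramp, no_expansion, 298.15, 0.0)
        assert tau == pytest.approx(30.0, rel=1e-12)

    def test_mid_ramp_value_against_bisection(self, geometry, no_expansion):
        ramp = make_ramp()
        tau = rk.residence_time_of_sample(geometry, ramp, no_expansion, 298.15, 360.0)
        assert tau / 60.0 == pytest.approx(0.931, abs=5e-4)
        assert tau == pytest.approx(tau_numeric(geometry, ramp, 1.0, 360.0), abs=1e-5)

    def test_closed_form_matches_numeric_inversion(self, geometry, no_expansion):
        """1000 random (Q0, alpha, t) draws: closed form vs numerical
        inversion of the sweep integral to < 1e-6 s."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            Q0 = rng.uniform(4.0, 15.0)
            alpha = rng.uniform(0.1, 1.2)
            ramp = make_ramp(Q0=Q0, Q_end=Q0 / 8, alpha=alpha, hold=20.0)
            t = rng.uniform(0.0, ramp.duration_min) * 60.0
            tau = rk.residence_time_of_sample(geometry, ramp, no_expansion, 298.15, t)
            assert tau == pytest.approx(
                tau_numeric(geometry, ramp, 1.0, t), abs=1e-6
            )
            checked += 1

    def test_continuity_as_alpha_vanishes(self, geometry, no_expansion):
        ramp = make_ramp(alpha=1e-9, Q_end=9.99)
        tau = rk.residence_time_of_sample(geometry, ramp, no_expansion, 298.15, 60.0)
        # the residual O(alpha) physical correction is ~5e-5 s here
        assert tau == pytest.approx(30.0, abs=1e-3)
        ramp0 = make_ramp(alpha=0.0)
        tau0 = rk.residence_time_of_sample(geometry, ramp0, no_expansion, 298.15, 60.0)
        assert tau0 == pytest.approx(30.0, rel=1e-14)

    def test_monotone_during_deceleration(self, geometry, no_expansion):
        ramp = make_ramp()
        taus = [
            rk.residence_time_of_sample(geometry, ramp, no_expansion, 298.15, t)
            for t in np.linspace(0, ramp.duration_min * 60, 25)
        ]
        assert np.all(np.diff(taus) > 0)

    def test_thermal_expansion_shortens_residence(self, geometry):
        ramp = make_ramp(T_C=120.0)
        hot = rk.ThermalExpansionModel()
        cold = rk.ThermalExpansionModel(alpha_v=0.0)
        tau_hot = rk.residence_time_of_sample(geometry, ramp, hot, 393.15, 120.0)
        tau_cold = rk.residence_time_of_sample(geometry, ramp, cold, 393.15, 120.0)
        assert tau_hot < tau_cold

    def test_unswept_reactor_is_schedule_error(self, no_expansion):
        big = rk.ReactorGeometry(volume_mL=500.0)
        ramp = make_ramp(hold=0.0)
        with pytest.raises(ScheduleError):
            rk.residence_time_of_sample(big, ramp, no_expansion, 298.15, 0.0)


class TestInletConcentrations:
    def test_no_nucleophile_pump(self):
        ramp = rk.RampProgram({"P1": 2.5, "P2": 7.5, "P3": 0.0}, 1.5, 0.836)
        c1, c2, eq = rk.inlet_concentrations(ramp, {"P1": 0.4, "P3": 2.0})
        assert (c2, eq) == (0.0, 0.0)

    def test_equal_stocks_equal_flows_gives_unit_equivalents(self):
        ramp = rk.RampProgram({"P1": 3.0, "P2": 4.0, "P3": 3.0}, 1.5, 0.836)
        _, _, eq = rk.inlet_concentrations(ramp, {"P1": 0.5, "P3": 0.5})
        assert eq == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("target", [1.5, 4.0, 7.0])
    def test_design_round_trip(self, design, target):
        """Pump splits solved for a target equivalents level reproduce it."""
        ramp = design.ramp_for(target, 90.0)
        _, _, eq = rk.inlet_concentrations(ramp, design.stock_concentrations())
        assert eq == pytest.approx(target, rel=1e-12)

    def test_zero_substrate_with_nucleophile_is_config_error(self):
        ramp = rk.RampProgram({"P1": 2.0, "P2": 5.0, "P3": 3.0}, 1.5, 0.836)
        with pytest.raises(ConfigError):
            rk.inlet_concentrations(ramp, {"P3": 2.0})


class TestInjectionSchedule:
    def test_default_campaign_has_72_points(self, design):
        pts = rk.build_injection_schedule(design)
        assert len(pts) == 72
        assert len({p.ramp_id for p in pts}) == 12
        # 6 injections per ramp: ramp lasts (10-1.5)/0.836 = 10.17 min
        for rid in {p.ramp_id for p in pts}:
            assert sum(p.ramp_id == rid for p in pts) == 6

    def test_single_injection_when_interval_exceeds_ramp(self):
        d = rk.CampaignDesign(
            equivalents_levels=(4.0,), temperatures_C=(90.0,),
            injection_interval_min=30.0,
        )
        pts = rk.build_injection_schedule(d)
        assert len(pts) == 1 and pts[0].t == 0.0

    @pytest.mark.parametrize("interval, per_ramp", [(2.0, 6), (1.0, 11), (4.0, 3)])
    def test_count_formula(self, interval, per_ramp):
        # count per ramp = floor(duration / dt) + 1
        d = rk.CampaignDesign(injection_interval_min=interval)
        pts = rk.build_injection_schedule(d)
        duration = (10.0 - 1.5) / 0.836
        assert per_ramp == math.floor(duration / interval) + 1
        assert len(pts) == 12 * per_ramp

    def test_deterministic(self, design):
        a = rk.build_injection_schedule(design)
        b = rk.build_injection_schedule(design)
        assert [(p.ramp_id, p.t, p.tau_res) for p in a] == [
            (p.ramp_id, p.t, p.tau_res) for p in b
        ]

    def test_invalid_interval(self):
        with pytest.raises(ConfigError):
            rk.CampaignDesign(injection_interval_min=-1.0).ramps()[0]


class TestGeometry:
    def test_length_area_volume_consistency(self, geometry):
        assert geometry.length * geometry.cross_section == pytest.approx(
            geometry.volume_m3, rel=1e-14
        )

    def test_coil_smaller_than_tube_rejected(self):
        with pytest.raises(ConfigError):
            rk.ReactorGeometry(d_t=1e-3, d_c=0.5e-3)
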