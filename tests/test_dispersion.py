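"""Dispersion analysis: dimensionless groups, Taylor–Aris coefficient,
closed-vessel conversion, rate-constant bias and F-curve estimation."""

import math
import warnings

import numpy as np
import pytest

import rampkin as rk
from rampkin.dispersion import TAYLOR_ARIS_DENOM, _f_curve_model
from rampkin.errors import ConfigError, DataError


class TestDimensionlessGroups:
    def test_reynolds_and_schmidt_values(self, ethanol):
        geom = rk.ReactorGeometry(d_c=10e-3)
        Re, Sc, De, DeSc05 = rk.dimensionless_groups(geom, ethanol, u=0.34)
        # hand arithmetic: Re = 789*0.34*0.79e-3/1.07e-3; Sc = mu/(rho Dm)
        assert Re == pytest.approx(198, abs=1.0)
        assert Sc == pytest.approx(1695, abs=5.0)
        assert De == pytest.approx(Re * math.sqrt(0.79e-3 / 10e-3), rel=1e-12)
        assert DeSc05 == pytest.approx(De * math.sqrt(Sc), rel=1e-12)

    def test_straight_tube_limit(self, ethanol):
        # De ~ 1/sqrt(d_c): an effectively straight tube has De -> 0
        des = []
        for d_c in (1e-2, 1e0, 1e3, 1e9):
            _, _, De, _ = rk.dimensionless_groups(
                rk.ReactorGeometry(d_c=d_c), ethanol, u=0.34
            )
            des.append(De)
        assert all(a > b for a, b in zip(des, des[1:]))
        assert des[-1] < 1e-3

    def test_missing_coil_diameter_is_config_error(self, ethanol, geometry):
        with pytest.raises(ConfigError, match="d_c"):
            rk.dimensionless_groups(geometry, ethanol, u=0.34)

    def test_groups_dimensionless_under_unit_rescaling(self, ethanol):
        """Re, Sc, De are invariant when all inputs are expressed in a
        rescaled, consistent unit system (here: time unit halved)."""
        geom = rk.ReactorGeometry(d_c=5e-3)
        a = rk.dimensionless_groups(geom, ethanol, u=0.2)
        # a time unit twice as long: numeric u, mu (Pa s) and D_m all halve
        fl2 = rk.FluidProperties(rho=789.0, mu=1.07e-3 / 2, D_m=0.8e-9 / 2)
        b = rk.dimensionless_groups(geom, fl2, u=0.1)
        for x, y in zip(a, b):
            assert x == pytest.approx(y, rel=1e-12)


class TestTaylorAris:
    def test_straight_tube_value(self, ethanol):
        u, d = 0.02834, 0.79e-3
        D = rk.taylor_aris_dispersion(u, d, ethanol.D_m, kappa=1.0)
        assert D == pytest.approx(
            ethanol.D_m + d**2 * u**2 / (192 * ethanol.D_m), rel=1e-12
        )

    def test_linear_in_kappa(self, ethanol):
        u, d = 0.1, 0.79e-3
        full = rk.taylor_aris_dispersion(u, d, ethanol.D_m, 1.0) - ethanol.D_m
        half = rk.taylor_aris_dispersion(u, d, ethanol.D_m, 0.5) - ethanol.D_m
        assert half == pytest.approx(full / 2, rel=1e-12)

    def test_no_flow_reduces_to_molecular_diffusion(self, ethanol):
        assert rk.taylor_aris_dispersion(0.0, 1e-3, ethanol.D_m, 1.0) == ethanol.D_m

    @pytest.mark.parametrize("kappa", [-0.1, 0.0, 1.5])
    def test_kappa_out_of_range(self, ethanol, kappa):
        with pytest.raises(ConfigError):
            rk.taylor_aris_dispersion(0.1, 1e-3, ethanol.D_m, kappa)


class TestKappaCorrelation:
    def test_laminar_limit_below_table(self):
        assert rk.kappa_from_correlation(0.5) == 1.0

    def test_monotone_non_increasing(self):
        xs = np.logspace(0.1, 3.9, 40)
        ks = [rk.kappa_from_correlation(x) for x in xs]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_clamped_above_table_with_warning(self):
        with pytest.warns(UserWarning, match="beyond"):
            k = rk.kappa_from_correlation(1e6)
        assert 0 < k <= 1

    def test_empty_table_rejected(self):
        with pytest.raises(ConfigError):
            rk.KappaCorrelation(table=())

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ConfigError):
            rk.KappaCorrelation(table=((1.0, 0.5), (2.0, 0.9)))


class TestClosedVesselConversion:
    def test_plug_flow_limit(self):
        """Vanishing dispersion recovers X = 1 - exp(-k tau)."""
        X, _ = rk.conversion_with_dispersion(1.0, 1.0, 1e-8)
        assert X == pytest.approx(1 - math.exp(-1.0), rel=1e-6)

    def test_mixed_flow_limit(self):
        """Infinite dispersion approaches X = k tau / (1 + k tau)."""
        X, _ = rk.conversion_with_dispersion(1.0, 1.0, 1e8)
        assert X == pytest.approx(0.5, rel=1e-6)

    def test_series_matches_exact_at_small_dispersion(self):
        Xf, af = rk.conversion_with_dispersion(1.0, 1.0, 0.01)
        Xs, as_, valid = rk.conversion_small_dispersion(1.0, 1.0, 0.01)
        assert valid
        assert abs(Xf - Xs) < 1e-4
        # the quadratic series for a is accurate to O((k tau N)^3)
        assert as_ == pytest.approx(af, abs=1e-5)

    def test_dispersion_reduces_conversion(self):
        X0, _ = rk.conversion_with_dispersion(2.0, 1.0, 0.0)
        Xs = [rk.conversion_with_dispersion(2.0, 1.0, N)[0]
              for N in (1e-3, 1e-2, 1e-1, 1.0)]
        assert all(x < X0 for x in Xs)
        assert all(a > b for a, b in zip(Xs, Xs[1:]))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigError):
            rk.conversion_with_dispersion(-1.0, 1.0, 0.1)


class TestRateConstantBias:
    def test_no_secondary_dispersion_no_bias(self, ethanol):
        k_obs, eps, _ = rk.rate_constant_bias(1.0, 0.3, 1e-3, ethanol.D_m, 0.0)
        assert eps == 0.0 and k_obs == 1.0

    def test_printed_evaluation_1mm_tube(self, ethanol):
        """For a 1 mm tube in ethanol the bias per unit kappa*k is
        about -500% s (pins the closed-form constant)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, eps, Da_r = rk.rate_constant_bias(1.0, 0.3, 1e-3, 0.8e-9, 1.0)
        assert 100 * eps == pytest.approx(-500.0, rel=1e-9)
        assert Da_r == pytest.approx(1e-6 / 0.8e-9, rel=1e-12)

    def test_always_underestimates(self, ethanol):
        rng = np.random.default_rng(9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(50):
                k = 10 ** rng.uniform(-3, 0.5)
                kap = rng.uniform(0.0, 1.0)
                d = 10 ** rng.uniform(-4, -2.5)
                k_obs, eps, _ = rk.rate_constant_bias(k, 0.1, d, ethanol.D_m, kap)
                assert eps <= 0.0 and k_obs <= k

    def test_monotone_in_kappa_k_and_diameter(self, ethanol):
        def mag(k, kap, d):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return abs(rk.rate_constant_bias(k, 0.1, d, ethanol.D_m, kap)[1])

        assert mag(0.1, 0.3, 1e-3) < mag(0.2, 0.3, 1e-3)
        assert mag(0.1, 0.3, 1e-3) < mag(0.1, 0.6, 1e-3)
        assert mag(0.1, 0.3, 0.5e-3) < mag(0.1, 0.3, 1e-3)

    def test_large_bias_warns(self, ethanol):
        with pytest.warns(UserWarning, match="small-dispersion"):
            rk.rate_constant_bias(1.0, 0.3, 1e-3, ethanol.D_m, 0.5)


class TestLumpedFirstOrder:
    def test_reference_values_at_unit_excess(self):
        assert rk.lumped_first_order(0.579, 0.027, 1.0) == pytest.approx(0.606)

    def test_zero_nucleophile(self):
        assert rk.lumped_first_order(0.579, 0.027, 0.0) == 0.0

    def test_linear_in_concentration(self):
        assert rk.lumped_first_order(0.3, 0.1, 0.4) == pytest.approx(
            2 * rk.lumped_first_order(0.3, 0.1, 0.2)
        )


class TestFCurve:
    @pytest.mark.parametrize("kappa", [0.05, 0.15, 0.31, 1.0])
    def test_round_trip(self, geometry, ethanol, kappa):
        """Generate a step response with a known dispersion ratio at the
        6-min operating point and recover it to < 3%."""
        u = geometry.length / 360.0
        t = np.linspace(1.0, 900.0, 400)
        F = rk.simulate_f_curve(geometry, ethanol, u, kappa, t)
        est = rk.estimate_kappa_from_f_curve(t, F, geometry, ethanol, u)
        assert est == pytest.approx(kappa, rel=0.03)

    def test_plug_flow_step_gives_zero_kappa(self, geometry, ethanol):
        u = geometry.length / 360.0
        t = np.linspace(1.0, 900.0, 200)
        F = (t >= 360.0).astype(float)
        with pytest.warns(UserWarning, match="not.*resolved|plug"):
            est = rk.estimate_kappa_from_f_curve(t, F, geometry, ethanol, u)
        assert est < 0.01

    def test_non_monotone_curve_rejected(self, geometry, ethanol):
        u = geometry.length / 360.0
        t = np.linspace(1.0, 900.0, 50)
        F = rk.simulate_f_curve(geometry, ethanol, u, 0.3, t)
        F[25] = F[24] - 0.2
        with pytest.raises(DataError):
            rk.estimate_kappa_from_f_curve(t, F, geometry, ethanol, u)

    def test_truncated_curve_rejected(self, geometry, ethanol):
        u = geometry.length / 360.0
        t = np.linspace(1.0, 300.0, 50)  # stops before the front passes
        F = rk.simulate_f_curve(geometry, ethanol, u, 0.3, t)
        with pytest.raises(DataError):
            rk.estimate_kappa_from_f_curve(t, F, geometry, ethanol, u)

    def test_model_midpoint_at_mean_residence_time(self):
        assert _f_curve_model(np.array([360.0]), 360.0, 0.01)[0] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def report(clean_table, scheme, geometry, ethanol):
    return rk.campaign_dispersion_report(
        clean_table, scheme, geometry, ethanol, kappa=0.15
    )


class TestCampaignReport:
    def test_twelve_profiles(self, report):
        assert len(report) == 12
        assert report["kappa"].eq(0.15).all()

    def test_bias_always_negative(self, report):
        assert (report["epsilon12_pct"] < 0).all()
        assert (report["epsilon34_pct"] < 0).all()

    def test_fully_converted_profile_masked(self, report):
        """At 120 C and 7 equivalents the substrate is exhausted at every
        sampled residence time, so the k1+k2 cell is uninformative."""
        hot = report[np.isclose(report["temp_C"], 120.0)
                     & np.isclose(report["equivalents"], 7.0)]
        assert bool(hot["masked12"].iloc[0])
        mild = report[np.isclose(report["temp_C"], 30.0)
                      & np.isclose(report["equivalents"], 1.5)]
        assert not bool(mild["masked12"].iloc[0])

    def test_zero_kappa_zeroes_all_entries(self, clean_table, scheme, geometry, ethanol):
        rep = rk.campaign_dispersion_report(
            clean_table, scheme, geometry, ethanol, kappa=0.0
        )
        assert (rep["epsilon12_pct"] == 0).all()
        assert (rep["epsilon34_pct"] == 0).all()
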