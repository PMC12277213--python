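import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from berryflux.phenology import ParameterError
from berryflux.water import (
    PressureState, WaterParams, extensibility, fruit_surface_area,
    fruit_volume, hydraulic_conductivity, osmotic_pressure,
    skin_permeability, solve_turgor, transpiration, water_mass_rate,
    water_uptake,
)


def make_params(**kw):
    base = dict(L_max=120.0, k_L=1.0, a_mem=0.03, sigma_p=0.95, sigma_x=0.95,
                rho_min=2.0, rho_0=22.0, k_p=3.0, H_f=0.996, Y=0.2,
                phi_max=0.012, t_phi=1200.0, s_phi=300.0, c_area=4.84,
                osm_other=1.0, rho_water=1000.0, rho_dry=1600.0)
    base.update(kw)
    return WaterParams(**base)


class TestGeometry:
    def test_volume_additivity(self):
        p = make_params()
        assert fruit_volume(0.0, 1000.0, p) == pytest.approx(1.0)
        assert fruit_volume(160.0, 0.0, p) == pytest.approx(0.1)
        assert fruit_volume(160.0, 840.0, p) == pytest.approx(0.94)

    def test_area_allometry(self):
        p = make_params()
        assert fruit_surface_area(1000.0, p) == pytest.approx(4.84)
        assert fruit_surface_area(8000.0, p) == pytest.approx(4 * 4.84)
        assert fruit_surface_area(0.0, p) == 0.0


class TestOsmoticPressure:
    def test_vant_hoff_reference(self):
        # 100 mol/m3 at 293.15 K: 8.314 * 293.15 * 100e-6 MPa
        assert osmotic_pressure(100.0, 293.15) == pytest.approx(0.2437,
                                                                abs=2e-4)

    def test_linear_in_concentration(self):
        pi1 = osmotic_pressure(50.0, 293.15)
        assert osmotic_pressure(100.0, 293.15) == pytest.approx(2 * pi1)
        assert osmotic_pressure(0.0, 293.15) == 0.0


class TestAbaModulation:
    def test_conductivity_limits(self):
        p = make_params(k_L=1.0)
        assert hydraulic_conductivity(0.0, p) == p.L_max
        assert hydraulic_conductivity(1.0, p) == pytest.approx(
            p.L_max * math.exp(-1.0), rel=1e-12)

    def test_permeability_limits_and_frozen_value(self):
        p = make_params(rho_min=20.0, rho_0=100.0, k_p=2.0)
        assert skin_permeability(0.0, p) == 120.0
        assert skin_permeability(0.5, p) == pytest.approx(
            20.0 + 100.0 * math.exp(-1.0), rel=1e-12)  # 56.79
        big_k = make_params(rho_min=20.0, rho_0=100.0, k_p=500.0)
        assert skin_permeability(1.0, big_k) == pytest.approx(20.0)

    def test_both_decrease_with_aba(self):
        p = make_params()
        u = np.linspace(0.0, 1.0, 50)
        L = [hydraulic_conductivity(x, p) for x in u]
        rho = [skin_permeability(x, p) for x in u]
        assert all(a > b for a, b in zip(L, L[1:]))
        assert all(a > b for a, b in zip(rho, rho[1:]))


class TestTranspiration:
    def test_no_gradient_no_loss(self):
        p = make_params(H_f=0.95)
        assert transpiration(5.0, 293.15, 0.95, 0.0, p) == 0.0
        # condensation clamped
        assert transpiration(5.0, 293.15, 1.0, 0.0, p) == 0.0

    def test_proportional_to_area(self):
        p = make_params()
        t1 = transpiration(5.0, 293.15, 0.6, 0.2, p)
        assert transpiration(10.0, 293.15, 0.6, 0.2, p) == pytest.approx(
            2 * t1, rel=1e-12)

    def test_magnitude_product(self):
        # A_f * alpha * rho * dH * 1000 with alpha(293.15) ~ 1.73e-5
        p = make_params(rho_min=0.0, rho_0=100.0, k_p=1.0)
        val = transpiration(5.0, 293.15, 0.596, 0.0, p)
        assert val == pytest.approx(5.0 * 1.73e-5 * 100.0 * 0.4 * 1000.0,
                                    rel=0.01)

    def test_non_increasing_in_aba(self):
        p = make_params()
        vals = [transpiration(5.0, 293.15, 0.6, u, p)
                for u in np.linspace(0, 1, 20)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestExtensibility:
    def test_limits_and_midpoint(self):
        p = make_params(phi_max=0.01, t_phi=900.0, s_phi=250.0)
        assert extensibility(-1e9, p) == 0.01
        assert extensibility(900.0, p) == pytest.approx(0.005)
        t10 = 900.0 + 250.0 * math.log(9.0)
        assert extensibility(t10, p) == pytest.approx(0.001, rel=1e-12)

    def test_monotone_decreasing(self):
        p = make_params()
        ts = np.linspace(0, 3000, 100)
        vals = [extensibility(t, p) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def unit_boundary(P_x=0.0, pi_x=0.0, P_p=0.0, pi_p=0.0):
    return PressureState(P_f=0.0, pi_f=0.0, P_x=P_x, pi_x=pi_x,
                         P_p=P_p, pi_p=pi_p)


class TestTurgorClosure:
    def test_linear_solve_and_flux_balance(self):
        # effective potentials 0.2 and 0.4 per pathway with A_m*L = 1,
        # transpiration-equivalent 0.1, V*phi = 1, Y = 0.1 (rho_water = 1)
        p = make_params(sigma_x=0.0, sigma_p=0.0, Y=0.1, rho_water=1.0)
        bound = unit_boundary(P_x=0.2, P_p=0.4)
        P_f, growth = solve_turgor(V=1.0, A_m=1.0, L=1.0, boundary=bound,
                                   pi_f=0.0, T_f=0.1, phi=1.0, params=p)
        assert P_f == pytest.approx(0.2, rel=1e-12)
        assert growth == pytest.approx(0.1, rel=1e-12)
        U_x, U_p = water_uptake(P_f, 0.0, bound, 1.0, 1.0, p)
        # net inflow - transpiration = growth (volume, rho_water = 1)
        assert U_x + U_p - 0.1 == pytest.approx(growth, rel=1e-12)

    def test_equilibrium_with_no_drivers(self):
        p = make_params(sigma_x=0.0, sigma_p=0.0, Y=0.5)
        bound = unit_boundary(P_x=0.3, P_p=0.3)
        P_f, growth = solve_turgor(V=1.0, A_m=1.0, L=1.0, boundary=bound,
                                   pi_f=0.0, T_f=0.0, phi=0.0, params=p)
        assert P_f == pytest.approx(0.3)
        assert growth == 0.0
        U_x, U_p = water_uptake(P_f, 0.0, bound, 1.0, 1.0, p)
        assert U_x == pytest.approx(0.0, abs=1e-12)
        assert U_p == pytest.approx(0.0, abs=1e-12)

    def test_isolated_fruit_shrinks_at_transpiration_rate(self):
        # L = 0: no vascular exchange; water loss = T_f exactly
        p = make_params(Y=0.1)
        bound = unit_boundary()
        P_f, growth = solve_turgor(V=1.0, A_m=1.0, L=0.0, boundary=bound,
                                   pi_f=1.0, T_f=2.0, phi=0.01, params=p)
        assert growth == 0.0
        U_x, U_p = water_uptake(P_f, 1.0, bound, 1.0, 0.0, p)
        assert water_mass_rate(U_x, U_p, 2.0) == -2.0

    def test_branch_continuity_at_yield(self):
        # drive the system so the solution sits exactly at P_f = Y:
        # below-yield solve and Lockhart solve must agree
        p = make_params(sigma_x=0.0, sigma_p=0.0, Y=0.25, rho_water=1.0)
        bound = unit_boundary(P_x=0.25, P_p=0.25)
        P_f, growth = solve_turgor(V=1.0, A_m=1.0, L=1.0, boundary=bound,
                                   pi_f=0.0, T_f=0.0, phi=1.0, params=p)
        assert P_f == pytest.approx(0.25, rel=1e-12)
        assert growth == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(psi=st.floats(-1.8, -0.1), pi_f=st.floats(0.0, 3.0),
           T_f=st.floats(0.0, 5.0), phi=st.floats(1e-5, 0.05),
           V=st.floats(1e-3, 3.0), G=st.floats(1e-3, 50.0))
    def test_solved_balance_residual(self, psi, pi_f, T_f, phi, V, G):
        """The turgor the closure returns satisfies the equation it solved."""
        p = make_params()
        pi_p = 0.2
        bound = PressureState(P_f=0.0, pi_f=pi_f, P_x=psi, pi_x=0.0,
                              P_p=psi + pi_p, pi_p=pi_p)
        P_f, growth = solve_turgor(V=V, A_m=1.0, L=G, boundary=bound,
                                   pi_f=pi_f, T_f=T_f, phi=phi, params=p)
        U_x, U_p = water_uptake(P_f, pi_f, bound, 1.0, G, p)
        if P_f > 0.0:
            residual = (U_x + U_p - T_f) / p.rho_water - growth
            scale = max(1.0, abs(U_x) + abs(U_p) + T_f)
            assert abs(residual) < 1e-10 * scale
        assert P_f >= 0.0
        assert growth >= 0.0


class TestWaterMassRate:
    @pytest.mark.parametrize("fluxes, expected", [
        ((0.0, 0.0, 0.0), 0.0),
        ((3.0, 2.0, 1.0), 4.0),
        ((-1.5, 2.5, 0.5), 0.5),
    ])
    def test_identity(self, fluxes, expected):
        assert water_mass_rate(*fluxes) == expected


class TestParamValidation:
    def test_sigma_range(self):
        with pytest.raises(ParameterError):
            make_params(sigma_x=1.5)

    def test_zero_extensibility_scale(self):
        with pytest.raises(ParameterError):
            make_params(s_phi=0.0)
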