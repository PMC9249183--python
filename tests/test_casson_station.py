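"""Per-station Casson closed forms: conductance, velocity, inversion, shear."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stenoflow import (
    ForceField,
    axial_velocity,
    conductance,
    drive,
    plug_radius_from_yield,
    plug_velocity,
    pressure_gradient,
    solve_station,
    wall_shear_stress,
)
from stenoflow.exceptions import (
    DegenerateStationError,
    DomainError,
    NoFlowError,
    PlugOverflowError,
)

# Conductance at (H=1, r0=0.2), frozen after agreement with the adaptive
# quadrature of the velocity profile (flux oracle) to machine precision.
G_1_02 = 0.030548496523821522

H_R0_GRID = [(H, r0) for H in (0.7, 0.85, 1.0, 1.1) for r0 in (0.0, 0.1, 0.2, 0.3)]


class TestConductance:
    @pytest.mark.parametrize(
        "H,r0,expected",
        [
            (1.0, 0.0, 0.125),  # Newtonian: only H^4/8 survives
            (0.8, 0.0, 0.8**4 / 8.0),
            (1.0, 0.2, G_1_02),  # quadrature-verified regression value
        ],
    )
    def test_known_values(self, H, r0, expected):
        assert conductance(H, r0) == pytest.approx(expected, rel=1e-12)

    def test_plug_overflow_rejected(self):
        with pytest.raises(PlugOverflowError):
            conductance(0.5, 0.6)

    def test_vectorized_over_stations(self):
        H = np.array([0.8, 0.9, 1.0])
        g = conductance(H, 0.1)
        assert g.shape == (3,)
        assert np.all(np.diff(g) > 0)  # wider lumen conducts more

    @given(st.floats(0.5, 1.2), st.floats(0.0, 0.99))
    def test_positive_below_lumen(self, H, frac):
        assert conductance(H, frac * H) > 0


class TestVelocityProfile:
    @pytest.mark.parametrize("H,r0", H_R0_GRID)
    def test_no_slip_exact(self, H, r0):
        assert axial_velocity(H, H, r0, 1.7) == 0.0

    def test_poiseuille_limit(self):
        r = np.linspace(0, 1, 11)
        u = axial_velocity(r, 1.0, 0.0, 1.0)
        np.testing.assert_allclose(u, 0.25 * (1 - r**2), atol=1e-15)

    def test_continuous_at_plug_boundary(self):
        u_edge = axial_velocity(0.2, 1.0, 0.2, 1.0)
        assert u_edge == pytest.approx(plug_velocity(1.0, 0.2, 1.0), abs=1e-15)

    def test_flat_core(self):
        r = np.linspace(0.0, 0.199, 7)
        u = axial_velocity(r, 1.0, 0.2, 1.3)
        assert np.ptp(u) == 0.0

    def test_out_of_range_radius(self):
        with pytest.raises(DomainError):
            axial_velocity(1.2, 1.0, 0.1, 1.0)

    @given(
        H=st.floats(0.6, 1.2),
        frac=st.floats(0.0, 0.9),
        D=st.floats(0.1, 3.0),
    )
    def test_monotone_profile_and_flat_slope_at_plug(self, H, frac, D):
        """u non-increasing on [r0, H] for positive drive; du/dr(r0+) ~ 0."""
        r0 = frac * H
        r = np.linspace(r0, H, 50)
        u = axial_velocity(r, H, r0, D)
        assert np.all(np.diff(u) <= 1e-12)
        if r0 > 1e-3:
            h = 1e-7 * (H - r0)
            slope = (axial_velocity(r0 + h, H, r0, D) - axial_velocity(r0, H, r0, D)) / h
            # tolerance scales with the profile's term magnitude D*H^2 because
            # the closed form cancels to a much smaller u near a wide plug
            assert abs(slope) <= 1e-6 * max(abs(plug_velocity(H, r0, D)), D * H**2 / 4)


class TestPlugVelocity:
    def test_newtonian_centerline(self):
        assert plug_velocity(1.0, 0.0, 2.0) == pytest.approx(2.0 / 4.0)

    def test_fully_yielded_to_wall_degenerate(self):
        assert plug_velocity(0.9, 0.9, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_matches_velocity_at_plug_edge(self):
        assert plug_velocity(1.0, 0.2, 1.0) == pytest.approx(
            axial_velocity(0.2, 1.0, 0.2, 1.0), abs=1e-16
        )


class TestPressureGradientInversion:
    def test_zero_flux_balance_paper_mode(self, caption_forces):
        P = pressure_gradient(0.0, 1.0, 0.2, caption_forces, "paper")
        assert P == pytest.approx(caption_forces.body_force)

    def test_modes_are_sign_opposites_without_body_force(self, no_forces):
        Pp = pressure_gradient(0.1, 0.9, 0.1, no_forces, "paper")
        Pd = pressure_gradient(0.1, 0.9, 0.1, no_forces, "derived")
        assert Pp == pytest.approx(-Pd, rel=1e-15)

    @pytest.mark.parametrize("H,r0", [(H, r0) for H, r0 in H_R0_GRID if r0 < H])
    def test_derived_mode_round_trip(self, H, r0, caption_forces):
        Q = 0.1
        P = pressure_gradient(Q, H, r0, caption_forces, "derived")
        back = conductance(H, r0) * (caption_forces.body_force + P)
        assert back == pytest.approx(Q, rel=1e-12)

    def test_degenerate_station(self, caption_forces):
        with pytest.raises(DegenerateStationError):
            pressure_gradient(0.1, 0.5, 0.5, caption_forces)


class TestWallShearStress:
    def test_newtonian_poiseuille_wss(self, no_forces):
        Q, H = 0.1, 0.8
        tau = wall_shear_stress(Q, H, 0.0, no_forces, "derived")
        assert tau == pytest.approx(4 * Q / H**3, rel=1e-13)

    def test_paper_mode_adds_body_force(self, caption_forces):
        Q, H, r0 = 0.1, 0.9, 0.2
        tp = wall_shear_stress(Q, H, r0, caption_forces, "paper")
        td = wall_shear_stress(Q, H, r0, caption_forces, "derived")
        assert tp - td == pytest.approx(caption_forces.body_force, rel=1e-13)

    def test_reference_identity_at_unit_radius(self, caption_forces):
        from stenoflow import reference_wss

        for mode in ("paper", "derived"):
            assert wall_shear_stress(0.1, 1.0, 0.2, caption_forces, mode) == pytest.approx(
                reference_wss(0.1, 0.2, caption_forces, mode)
            )


class TestPlugRadiusFromYield:
    def test_newtonian_fluid_has_no_plug(self):
        assert plug_radius_from_yield(0.0, 1.0) == 0.0

    def test_direct_arithmetic(self):
        assert plug_radius_from_yield(0.1, 1.0) == pytest.approx(0.2)

    def test_no_flow_condition(self):
        with pytest.raises(NoFlowError):
            plug_radius_from_yield(0.1, 0.0)

    def test_overflow_against_lumen(self):
        with pytest.raises(PlugOverflowError):
            plug_radius_from_yield(0.5, 1.0, lumen_radius=0.9)


class TestStationSolution:
    def test_fields_are_mutually_consistent(self, caption_forces):
        sol = solve_station(0.9, 0.1, 0.2, caption_forces, "paper")
        assert sol.drive == pytest.approx(caption_forces.body_force + sol.pressure_gradient)
        assert sol.velocity(0.9) == 0.0
        assert sol.velocity(0.1) == pytest.approx(sol.plug_velocity)
        assert sol.drive == pytest.approx(
            drive(0.1, 0.9, 0.2, caption_forces, "paper"), rel=1e-14
        )

    def test_force_field_derived_quantities(self):
        f = ForceField(magnetization=2.0, gravity=0.3, inclination=math.pi / 6)
        assert f.axial_gravity == pytest.approx(0.15)
        assert f.body_force == pytest.approx(2.15)
        assert ForceField(1.0, 0.3, 0.0).axial_gravity == 0.0
        assert ForceField(1.0, 0.0, 1.0).axial_gravity == 0.0


class TestNewtonianCollapse:
    def test_all_limits_simultaneously(self, no_forces):
        """r0 -> 0 recovers parabola, g = H^4/8, tau_w = 4Q/H^3 together."""
        H, Q = 0.85, 0.2
        r = np.linspace(0, H, 9)
        np.testing.assert_allclose(
            axial_velocity(r, H, 0.0, 1.0), 0.25 * (H**2 - r**2), atol=1e-15
        )
        assert conductance(H, 0.0) == pytest.approx(H**4 / 8, rel=1e-15)
        assert wall_shear_stress(Q, H, 0.0, no_forces, "derived") == pytest.approx(
            4 * Q / H**3, rel=1e-13
        )
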