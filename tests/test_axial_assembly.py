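"""Axial integration: pressure drop, impedance, normalized quantities."""

import numpy as np
import pytest

from stenoflow import (
    AbnormalSegment,
    ForceField,
    VesselGeometry,
    conductance,
    impedance,
    normalized_impedance,
    normalized_wss,
    pressure_drop,
    reference_impedance,
    reference_wss,
    solve,
    wall_shear_stress,
    wss_profile,
)
from stenoflow.exceptions import (
    GeometryError,
    PlugOverflowError,
    UndefinedImpedanceError,
)

# Impedance at the anchor parameter set (paper mode), frozen as a smoke
# regression value after the flux/shear oracles agreed.
LAMBDA_CAPTION = -14.27252899638074

Q = 0.1
R0 = 0.2


def two_lesion_geometry(d1=0.1, d2=0.1):
    return VesselGeometry(
        segments=(
            AbnormalSegment.stenosis(d1, 0.2, 0.2),
            AbnormalSegment.dilatation(d2, 0.2, 0.6),
        )
    )


class TestPressureDrop:
    def test_uniform_tube_is_constant_integrand(self, caption_forces):
        geo = VesselGeometry(domain_length=1.0)
        dp = pressure_drop(Q, geo, R0, caption_forces, "paper")
        expected = (-Q / conductance(1.0, R0) + caption_forces.body_force) * 1.0
        assert dp == pytest.approx(expected, rel=1e-12)

    def test_zero_height_lesions_match_uniform_formula(self, caption_forces):
        geo = two_lesion_geometry(0.0, 0.0)
        dp = pressure_drop(Q, geo, R0, caption_forces, "paper")
        expected = (-Q / conductance(1.0, R0) + caption_forces.body_force) * geo.length
        assert dp == pytest.approx(expected, rel=1e-13)

    def test_quadrature_converges_under_node_doubling(self, caption_forces):
        geo = two_lesion_geometry()
        dp1 = pressure_drop(Q, geo, R0, caption_forces, "paper", quadrature_points=2001)
        dp2 = pressure_drop(Q, geo, R0, caption_forces, "paper", quadrature_points=4001)
        assert abs(dp2 - dp1) / abs(dp1) < 1e-8

    def test_simpson_convergence_rate(self, caption_forces):
        """Richardson node-doubling error shrinks at (at least) 4th order."""
        geo = two_lesion_geometry()
        ref = pressure_drop(Q, geo, R0, caption_forces, "paper", quadrature_points=8001)
        errs = [
            abs(pressure_drop(Q, geo, R0, caption_forces, "paper", quadrature_points=n) - ref)
            for n in (51, 101, 201)
        ]
        assert errs[1] < errs[0] / 8
        assert errs[2] < errs[1] / 8

    def test_plug_overflow_at_throat(self, caption_forces):
        geo = two_lesion_geometry(0.3, 0.1)  # min H = 0.7
        with pytest.raises(PlugOverflowError):
            pressure_drop(Q, geo, 0.75, caption_forces)


class TestImpedance:
    def test_uniform_tube_scaling(self, caption_forces):
        geo = VesselGeometry(domain_length=1.0)
        lam = impedance(Q, geo, R0, caption_forces, "paper")
        assert lam == pytest.approx(10 * pressure_drop(Q, geo, R0, caption_forces, "paper"))

    def test_linearity_in_flux_without_body_force(self, no_forces):
        geo = two_lesion_geometry()
        lam1 = impedance(0.1, geo, R0, no_forces, "derived")
        lam2 = impedance(0.2, geo, R0, no_forces, "derived")
        assert lam1 == pytest.approx(lam2, rel=1e-12)

    def test_caption_regression_value(self, caption_forces):
        lam = impedance(Q, two_lesion_geometry(), R0, caption_forces, "paper")
        assert lam == pytest.approx(LAMBDA_CAPTION, rel=1e-9)

    def test_zero_flux_rejected(self, caption_forces):
        with pytest.raises(UndefinedImpedanceError):
            impedance(0.0, two_lesion_geometry(), R0, caption_forces)


class TestReferenceQuantities:
    def test_reference_equals_empty_geometry(self, caption_forces):
        geo = VesselGeometry(domain_length=1.2)
        for mode in ("paper", "derived"):
            assert reference_impedance(Q, R0, caption_forces, mode, 1.2) == pytest.approx(
                impedance(Q, geo, R0, caption_forces, mode), rel=1e-12
            )

    def test_poiseuille_reference_impedance(self, no_forces):
        # r0 = 0, unit length, derived mode: lambda_n = 8 (Delta p = Q / (1/8))
        assert reference_impedance(Q, 0.0, no_forces, "derived", 1.0) == pytest.approx(8.0)

    def test_reference_independent_of_geometry(self, caption_forces):
        a = reference_impedance(Q, R0, caption_forces, "paper", 1.2)
        b = reference_impedance(Q, R0, caption_forces, "paper", 1.2)
        assert a == b

    def test_newtonian_reference_wss(self, no_forces):
        assert reference_wss(Q, 0.0, no_forces, "derived") == pytest.approx(4 * Q)

    def test_reference_wss_definitional(self, caption_forces):
        for mode in ("paper", "derived"):
            assert reference_wss(Q, R0, caption_forces, mode) == wall_shear_stress(
                Q, 1.0, R0, caption_forces, mode
            )


class TestNormalizedQuantities:
    @pytest.mark.parametrize("mode", ["paper", "derived"])
    def test_normalization_identities_without_lesions(self, mode, caption_forces):
        geo = two_lesion_geometry(0.0, 0.0)
        assert normalized_impedance(Q, geo, R0, caption_forces, mode) == pytest.approx(
            1.0, abs=1e-12
        )
        assert normalized_wss(Q, geo, R0, caption_forces, mode) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_lambda_bar_monotone_in_stenosis_height(self, caption_forces):
        vals = [
            normalized_impedance(Q, two_lesion_geometry(d, 0.1), R0, caption_forces, "paper")
            for d in (0.05, 0.10, 0.15)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_lambda_bar_monotone_in_dilatation_height(self, caption_forces):
        vals = [
            normalized_impedance(Q, two_lesion_geometry(0.1, d), R0, caption_forces, "paper")
            for d in (0.05, 0.10, 0.15)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_tau_bar_monotone_in_stenosis_height_at_throat(self, caption_forces):
        vals = [
            normalized_wss(Q, two_lesion_geometry(d, 0.1), R0, caption_forces, "paper")
            for d in (0.05, 0.10, 0.15)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_unit_ratio_outside_lesions(self, caption_forces):
        geo = two_lesion_geometry()
        assert normalized_wss(Q, geo, R0, caption_forces, "paper", station=0.7) == 1.0

    def test_throat_requires_a_lesion(self, caption_forces):
        with pytest.raises(GeometryError):
            normalized_wss(Q, VesselGeometry(), R0, caption_forces, "paper", "throat")

    def test_mode_antisymmetry_without_body_force(self, no_forces):
        geo = two_lesion_geometry()
        lam_p = impedance(Q, geo, R0, no_forces, "paper")
        lam_d = impedance(Q, geo, R0, no_forces, "derived")
        assert lam_p == pytest.approx(-lam_d, rel=1e-12)
        assert normalized_impedance(Q, geo, R0, no_forces, "paper") == pytest.approx(
            normalized_impedance(Q, geo, R0, no_forces, "derived"), rel=1e-12
        )


class TestSolve:
    def test_assembled_solution_consistency(self, caption_config):
        cfg = caption_config
        sol = solve(cfg.flux, cfg.geometry, cfg.plug_radius, cfg.forces, cfg.mode)
        assert sol.normalized_impedance == pytest.approx(
            sol.impedance / sol.reference_impedance
        )
        assert sol.abs_pressure_drop == abs(sol.pressure_drop)
        assert sol.evaluation_station == pytest.approx(0.3)  # first throat
        prof = sol.wall_shear_profile
        assert list(prof.columns) == ["z", "H", "P", "tau_w"]
        assert np.isfinite(prof.to_numpy()).all()

    def test_wss_profile_reduces_to_reference_outside_lesions(self, caption_forces):
        geo = two_lesion_geometry()
        prof = wss_profile(np.array([0.0, 0.7, 0.9]), Q, geo, R0, caption_forces, "paper")
        ref = reference_wss(Q, R0, caption_forces, "paper")
        np.testing.assert_allclose(prof["tau_w"], ref, rtol=1e-14)
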