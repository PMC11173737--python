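"""Closed-form hydration thermodynamics: values, invariants, fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hydroshape as hs
from hydroshape.errors import DegenerateDataError, DomainError, InsufficientDataError


class TestSphericalRadius:
    def test_water_molecular_volume_gives_effective_radius(self):
        # ambient molecular volume of water -> r_H2O to 2 significant figures
        r = hs.spherical_radius_from_volume(3e-29)
        assert f"{r:.2g}" == "1.9"

    def test_unit_sphere_construction(self):
        assert hs.spherical_radius_from_volume(4 * math.pi / 3 * 1e-30) == pytest.approx(1.0)

    def test_cube_root_scaling(self):
        r1 = hs.spherical_radius_from_volume(3e-29)
        r8 = hs.spherical_radius_from_volume(8 * 3e-29)
        assert r8 == pytest.approx(2 * r1, rel=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DomainError):
            hs.spherical_radius_from_volume(0.0)


class TestInterfacialRatio:
    def test_cancellation_at_four_water_radii(self, ambient):
        assert hs.interfacial_volume_ratio_sphere(4 * ambient.r_h2o, ambient) == pytest.approx(1.0)
        assert hs.interfacial_volume_ratio_sphere(7.6, ambient) == pytest.approx(1.0)

    def test_direct_arithmetic(self, ambient):
        assert hs.interfacial_volume_ratio_sphere(6.5, ambient) == pytest.approx(4 * 1.9 / 6.5)

    def test_nonpositive_radius_rejected(self, ambient):
        with pytest.raises(DomainError):
            hs.interfacial_volume_ratio_sphere(-1.0, ambient)


class TestSoluteWaterTerm:
    def test_no_bonds_lost_is_zero(self, ambient):
        assert hs.solute_water_free_energy(5.0, ambient, n_hb=0) == 0.0

    def test_vanishes_at_large_radius(self, ambient):
        assert abs(hs.solute_water_free_energy(1e12, ambient)) < 1e-9

    def test_reference_value_at_critical_size(self, ambient):
        # 8 * (-2.66) * 1.9 / 6.5
        assert hs.solute_water_free_energy(6.5, ambient) == pytest.approx(
            -6.220307692307692, rel=1e-12
        )

    def test_interfacial_term_factor_of_eight(self, ambient):
        # two lost bonds per interfacial molecule <=> the 8 r_H2O/R term
        rng = np.random.default_rng(0)
        for radius in rng.uniform(0.5, 50.0, 100):
            expected = 8 * ambient.dg_ddaa * ambient.r_h2o / radius
            assert hs.solute_water_free_energy(float(radius), ambient, n_hb=2) == pytest.approx(
                expected, rel=1e-9
            )


class TestHydrationFreeEnergy:
    def test_bulk_limit(self, ambient):
        assert hs.hydration_free_energy(1e12, ambient) == pytest.approx(
            ambient.dg_water_water, rel=1e-9
        )

    def test_terms_balance_at_critical_radius(self, ambient):
        rc = hs.critical_radius(ambient)
        assert abs(hs.solute_water_free_energy(rc, ambient)) == pytest.approx(
            abs(ambient.dg_water_water), rel=1e-9
        )

    def test_sum_of_reference_terms(self, ambient):
        assert hs.hydration_free_energy(6.5, ambient) == pytest.approx(
            ambient.dg_water_water - 6.220307692307692, rel=1e-9
        )

    @given(st.floats(min_value=0.5, max_value=500.0), st.floats(min_value=0.5, max_value=500.0))
    def test_strictly_monotone_in_inverse_radius(self, r1, r2):
        ambient = hs.ThermoConstants.ambient()
        if r1 == r2:
            return
        small, large = min(r1, r2), max(r1, r2)
        # dG_DDAA < 0: the interfacial penalty relaxes toward the bulk value
        assert hs.hydration_free_energy(small, ambient) < hs.hydration_free_energy(large, ambient)


class TestCriticalRadius:
    def test_literature_constants_give_reference_radius(self, ambient):
        assert hs.critical_radius(ambient) == pytest.approx(6.5, abs=0.1)

    def test_linear_in_bond_energy(self, ambient):
        halved = hs.ThermoConstants(
            dg_ddaa=ambient.dg_ddaa / 2, dg_water_water=ambient.dg_water_water,
            r_h2o=ambient.r_h2o,
        )
        assert hs.critical_radius(halved) == pytest.approx(hs.critical_radius(ambient) / 2)

    def test_cancellation(self):
        c = hs.ThermoConstants(dg_ddaa=-1.0, dg_water_water=-1.0, r_h2o=1.0)
        assert hs.critical_radius(c) == pytest.approx(8.0)

    def test_zero_bulk_term_rejected(self):
        c = hs.ThermoConstants(dg_ddaa=-1.0, dg_water_water=0.0, r_h2o=1.0)
        with pytest.raises(DomainError):
            hs.critical_radius(c)


class TestGeometricFactor:
    def test_identical_ratios(self):
        inp = hs.GeometricFactorInput(0.3, 0.3, 2.0, 5.0)
        assert hs.geometric_factor(inp) == 1.0

    def test_separated_solutes_share_no_surface(self):
        # beyond the hydrophobic radius the factor is exactly 1
        inp = hs.GeometricFactorInput(0.1, 0.9, 7.0, 5.0)
        assert hs.geometric_factor(inp) == 1.0

    def test_direct_division_in_contact(self):
        inp = hs.GeometricFactorInput(0.2, 0.4, 2.0, 5.0)
        assert hs.geometric_factor(inp) == pytest.approx(0.5)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(DomainError):
            hs.GeometricFactorInput(-0.1, 0.4, 2.0, 5.0)


class TestTransitionEnergy:
    def test_zero_count(self, ambient):
        assert hs.hydrophobic_interaction_energy(0, ambient) == 0.0

    def test_single_molecule_worth(self, ambient):
        assert hs.hydrophobic_interaction_energy(1, ambient) == pytest.approx(-2.66)

    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=0, max_value=10_000))
    def test_additive_in_count(self, n1, n2):
        ambient = hs.ThermoConstants.ambient()
        assert hs.hydrophobic_interaction_energy(n1 + n2, ambient) == pytest.approx(
            hs.hydrophobic_interaction_energy(n1, ambient)
            + hs.hydrophobic_interaction_energy(n2, ambient)
        )

    def test_negative_count_rejected(self, ambient):
        with pytest.raises(DomainError):
            hs.hydrophobic_interaction_energy(-1, ambient)


class TestWaterInducedModel:
    COEFFS = hs.WaterInducedModel(a=-21.01, b=27.62, r0=1.75, gamma=1.0)

    def test_asymptote(self):
        assert hs.evaluate_water_induced_model(1e9, self.COEFFS) == pytest.approx(
            self.COEFFS.a, abs=1e-6
        )

    def test_algebraic_zero_crossing(self):
        # at r = r0 + b/|a| the hyperbola exactly cancels the offset
        r = self.COEFFS.r0 + self.COEFFS.b / abs(self.COEFFS.a)
        assert hs.evaluate_water_induced_model(r, self.COEFFS) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_gamma(self):
        half = hs.WaterInducedModel(a=self.COEFFS.a, b=self.COEFFS.b, r0=1.75, gamma=0.5)
        r = 4.0
        full_term = hs.evaluate_water_induced_model(r, self.COEFFS) - self.COEFFS.a
        half_term = hs.evaluate_water_induced_model(r, half) - half.a
        assert half_term == pytest.approx(full_term / 2)

    def test_domain_boundary_rejected(self):
        with pytest.raises(DomainError):
            hs.evaluate_water_induced_model(1.75, self.COEFFS)


class TestWaterInducedFit:
    def test_noiseless_exact_recovery(self):
        truth = hs.WaterInducedModel(a=-21.01, b=27.62, r0=1.75, gamma=1.0)
        r = np.linspace(2.5, 12.0, 30)
        pts = np.column_stack([r, hs.evaluate_water_induced_model(r, truth)])
        fit = hs.fit_water_induced_model(pts, r0=1.75)
        assert fit.model.a == pytest.approx(truth.a, abs=1e-8)
        assert fit.model.b == pytest.approx(truth.b, abs=1e-8)
        assert np.allclose(fit.predict(r), pts[:, 1], atol=1e-8)

    def test_noisy_recovery_within_three_stderr(self):
        truth = hs.WaterInducedModel(a=-21.01, b=27.62, r0=1.75, gamma=1.0)
        rng = np.random.default_rng(11)
        r = np.linspace(2.5, 12.0, 50)
        y = hs.evaluate_water_induced_model(r, truth) + rng.normal(0, 0.5, r.size)
        fit = hs.fit_water_induced_model(np.column_stack([r, y]), r0=1.75)
        assert abs(fit.model.a - truth.a) < 3 * fit.a_stderr
        assert abs(fit.model.b - truth.b) < 3 * fit.b_stderr

    def test_constant_data_gives_zero_amplitude(self):
        r = np.linspace(3.0, 9.0, 12)
        fit = hs.fit_water_induced_model(np.column_stack([r, np.full(r.size, -5.0)]), r0=1.75)
        assert fit.model.b == pytest.approx(0.0, abs=1e-9)
        assert fit.model.a == pytest.approx(-5.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            hs.fit_water_induced_model([(2.0, 1.0), (3.0, 2.0)], r0=1.75)

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(DegenerateDataError):
            hs.fit_water_induced_model([(3.0, 1.0), (3.0, 2.0), (3.0, 3.0)], r0=1.75)


class TestPackingParameter:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.25, "sphere"),
            (0.40, "cylinder"),
            (0.75, "bilayer"),
            (1.5, "out-of-range"),
            (1.0 / 3.0, "sphere"),  # boundaries go to the smaller class
            (0.5, "cylinder"),
            (1.0, "bilayer"),
        ],
    )
    def test_interval_rule(self, p, expected):
        inp = hs.PackingParameterInput(v0=p, a_head=1.0, l0=1.0)
        assert hs.packing_parameter_shape(inp) == expected

    @given(
        st.floats(min_value=0.05, max_value=2.0),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_invariant_under_similarity_scaling(self, p, a_head, l0, k):
        # (v0, a, l0) -> (k^3 v0, k^2 a, k l0) leaves p and the class unchanged
        v0 = p * a_head * l0
        base = hs.PackingParameterInput(v0=v0, a_head=a_head, l0=l0)
        scaled = hs.PackingParameterInput(v0=k**3 * v0, a_head=k**2 * a_head, l0=k * l0)
        assert hs.packing_parameter_shape(base) == hs.packing_parameter_shape(scaled)

    def test_nonpositive_field_rejected(self):
        with pytest.raises(DomainError):
            hs.PackingParameterInput(v0=0.0, a_head=1.0, l0=1.0)


class TestConstants:
    def test_calorie_conversion_applied(self, ambient):
        assert ambient.dg_water_water == pytest.approx(-1.5 * 4.184)

    def test_mixed_sign_convention_rejected(self):
        with pytest.raises(DomainError):
            hs.ThermoConstants(dg_ddaa=-2.66, dg_water_water=+6.276)

    def test_from_config_kj_override(self):
        c = hs.ThermoConstants.from_config({"dG_water_water_kJ_mol": -6.0})
        assert c.dg_water_water == -6.0
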