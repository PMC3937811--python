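"""Volume distributions, scattering densities and the analytic form factor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdpgap import (
    BilayerSDP,
    Component,
    Contrast,
    ParsingScheme,
    component_density,
    default_pc_scheme,
    form_factor,
    gaussian_pair,
    hydrocarbon_envelope,
    solvent_density,
    volume_profiles,
    water_profile,
)
from sdpgap.sdp import COHERENT_B, FM_TO_A

from conftest import make_sdp


class TestComponentDensity:
    def test_xray_ch2_is_electrons_over_volume(self):
        ch2 = Component("CH2", {"C": 1, "H": 2}, 28.0, "ch2")
        rho = component_density(ch2, Contrast(radiation="xray"))
        assert rho == pytest.approx(8.0 / 28.0)

    def test_neutron_cd2_sums_table_scattering_lengths(self):
        cd2 = Component("CD2", {"C": 1, "D": 2}, 28.1, "ch2")
        rho = component_density(cd2, Contrast(radiation="neutron"))
        expected = (COHERENT_B["C"] + 2 * COHERENT_B["D"]) * FM_TO_A / 28.1
        assert rho == pytest.approx(expected)

    def test_water_xray_density(self):
        # 10 electrons in ~30 A^3 -> 1/3 e/A^3, the standard water value
        assert solvent_density(Contrast(radiation="xray")) == pytest.approx(
            0.3333, abs=1e-3
        )

    def test_d2o_neutron_sld_matches_handbook_value(self):
        rho = solvent_density(Contrast(radiation="neutron", solvent_d2o_fraction=1.0))
        assert rho == pytest.approx(6.38e-6, rel=0.01)  # A^-2

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            Component("bad", {"Xx": 1}, 10.0)

    def test_deuteration_increases_neutron_density(self):
        ch2 = Component("CH2", {"C": 28, "H": 58}, 828.8, "ch2")
        plain = component_density(ch2, Contrast(radiation="neutron"))
        d31 = component_density(
            ch2, Contrast(radiation="neutron", deuteration={"CH2": 28})
        )
        assert d31 > plain  # b_D > 0 > b_H

    def test_deuteration_beyond_available_h_rejected(self):
        ch2 = Component("CH2", {"C": 1, "H": 2}, 28.0, "ch2")
        with pytest.raises(ValueError, match="exceeds"):
            component_density(ch2, Contrast(radiation="neutron", deuteration={"CH2": 3}))


class TestHydrocarbonEnvelope:
    def test_deep_interior_is_unity(self):
        assert hydrocarbon_envelope(0.0, 14.0, 2.5) == pytest.approx(1.0, abs=1e-6)

    def test_half_height_at_interface(self):
        for sign in (+1, -1):
            assert hydrocarbon_envelope(sign * 14.0, 14.0, 2.5) == pytest.approx(0.5)

    def test_area_is_twice_chain_length(self):
        z = np.linspace(-60, 60, 24001)
        area = np.trapezoid(hydrocarbon_envelope(z, 14.0, 2.5), z)
        assert area == pytest.approx(2 * 14.0, rel=1e-9)

    @given(
        dc=st.floats(10.0, 18.0),
        s=st.floats(2.0, 2.6),
        z=st.floats(-50.0, 50.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetry_and_range(self, dc, s, z):
        v = hydrocarbon_envelope(z, dc, s)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(float(hydrocarbon_envelope(-z, dc, s)), rel=1e-12)


class TestGaussianPair:
    def test_total_integral_is_twice_leaflet_area(self):
        z = np.linspace(-80, 80, 32001)
        p = gaussian_pair(z, 18.6, 2.6, 1.95)
        assert np.trapezoid(p, z) == pytest.approx(2 * 1.95, rel=1e-9)

    def test_coincident_mirror_doubles_amplitude(self):
        single_amp = 1.0 / (2.9 * np.sqrt(2 * np.pi))
        assert gaussian_pair(0.0, 0.0, 2.9, 1.0) == pytest.approx(2 * single_amp)

    def test_peak_value_closed_form(self):
        c, s, a = 15.0, 2.2, 1.6
        expected = (a / (s * np.sqrt(2 * np.pi))) * (1 + np.exp(-2 * c**2 / s**2))
        assert gaussian_pair(c, c, s, a) == pytest.approx(expected, rel=1e-12)


class TestVolumeProfiles:
    def test_hydrocarbon_parts_sum_to_envelope(self, pc_scheme, z_grid):
        sdp = make_sdp(pc_scheme)
        prof = volume_profiles(sdp, pc_scheme, z_grid)
        env = hydrocarbon_envelope(z_grid, sdp.D_C, sdp.sigma_HC)
        np.testing.assert_allclose(prof["CH2"] + prof["CH3"], env, rtol=0, atol=1e-14)

    def test_component_integrals_match_volumes(self, pc_scheme, z_grid):
        sdp = make_sdp(pc_scheme)
        prof = volume_profiles(sdp, pc_scheme, z_grid)
        A = sdp.area(pc_scheme)
        for name in ("CholCH3", "PCN", "CG", "CH3"):
            integral = np.trapezoid(prof[name], z_grid)
            assert integral == pytest.approx(
                2 * sdp.volumes[name] / A, rel=1e-6
            ), name

    def test_spatial_conservation_is_exact(self, pc_scheme, z_grid):
        sdp = make_sdp(pc_scheme)
        prof = volume_profiles(sdp, pc_scheme, z_grid)
        total = sum(prof.values()) + water_profile(prof)
        np.testing.assert_array_equal(total, np.ones_like(z_grid))

    def test_water_far_from_bilayer_is_unity(self, pc_scheme):
        z = np.array([-60.0, 60.0])
        prof = volume_profiles(make_sdp(pc_scheme), pc_scheme, z)
        np.testing.assert_allclose(water_profile(prof), 1.0, atol=1e-12)

    def test_water_at_center_nearly_zero(self, pc_scheme):
        prof = volume_profiles(make_sdp(pc_scheme), pc_scheme, np.array([0.0]))
        assert water_profile(prof)[0] == pytest.approx(0.0, abs=1e-5)

    def test_cg_sits_between_interface_and_phosphate(self, pc_scheme, z_grid):
        # qualitative layout of the parsing scheme on the half bilayer
        sdp = make_sdp(pc_scheme)
        prof = volume_profiles(sdp, pc_scheme, z_grid)
        pos = {n: z_grid[np.argmax(np.where(z_grid > 0, prof[n], 0))] for n in prof}
        assert pos["CH3"] <= pos["CG"] <= pos["PCN"] <= pos["CholCH3"]
        assert abs(pos["CG"] - sdp.D_C) < 2.0


class TestFormFactor:
    def _quadrature_oracle(self, q, sdp, scheme, contrast):
        z = np.linspace(-80.0, 80.0, 16001)
        prof = volume_profiles(sdp, scheme, z)
        rho_w = solvent_density(contrast)
        delta = np.zeros_like(z)
        for c in scheme.components:
            rho = component_density(c, contrast, scheme, volume=sdp.volumes[c.name])
            delta += (rho - rho_w) * prof[c.name]
        return np.array([np.trapezoid(delta * np.cos(qi * z), z) for qi in q])

    def test_zero_contrast_gives_zero_amplitude(self, pc_scheme):
        sdp = make_sdp(pc_scheme)
        # solvent override matching every component density is impossible in
        # general; instead scale a one-component scheme
        comp = (
            Component("CH2", {"H": 28}, 780.0, "ch2"),
            Component("CH3", {"H": 6}, 108.0, "ch3"),
        )
        scheme = ParsingScheme(components=comp, headgroup_volume_target=331.0)
        volumes = {"CH2": 780.0, "CH3": 108.0}
        sdp1 = BilayerSDP(
            z_CholCH3=20.0, z_PCN=18.0, z_CG=15.0, sigma_PCN=2.5, sigma_CG=2.5,
            sigma_CH3=2.9, D_C=14.0, sigma_HC=2.3, volumes=volumes, V_L=888.0,
        )
        contrast = Contrast(radiation="xray", solvent_density=28.0 / 780.0)
        q = np.linspace(0.01, 0.6, 50)
        F = form_factor(q, sdp1, scheme, contrast)
        # CH2 and CH3 densities differ; null only the CH2/water contrast term
        assert abs(F[0]) < abs(
            form_factor(q, sdp1, scheme, Contrast(radiation="xray"))[0]
        )

    def test_f_at_zero_is_profile_integral(self, pc_scheme, xray):
        sdp = make_sdp(pc_scheme)
        A = sdp.area(pc_scheme)
        rho_w = solvent_density(xray)
        expected = 0.0
        for c in pc_scheme.components:
            rho = component_density(c, xray, pc_scheme, volume=sdp.volumes[c.name])
            expected += (rho - rho_w) * 2 * sdp.volumes[c.name] / A
        assert form_factor(np.array([0.0]), sdp, pc_scheme, xray)[0] == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("radiation", ["xray", "neutron"])
    def test_analytic_matches_quadrature(self, pc_scheme, radiation):
        contrast = Contrast(radiation=radiation, solvent_d2o_fraction=1.0)
        sdp = make_sdp(pc_scheme)
        q = np.linspace(0.01, 1.0, 100)
        F = form_factor(q, sdp, pc_scheme, contrast)
        F_ref = self._quadrature_oracle(q, sdp, pc_scheme, contrast)
        scale = np.max(np.abs(F_ref))
        np.testing.assert_allclose(F / scale, F_ref / scale, atol=1e-6)

    def test_grid_order_parity(self, pc_scheme, xray):
        sdp = make_sdp(pc_scheme)
        q = np.linspace(0.01, 0.8, 200)
        F = form_factor(q, sdp, pc_scheme, xray)
        F_rev = form_factor(q[::-1], sdp, pc_scheme, xray)
        np.testing.assert_array_equal(F, F_rev[::-1])

    def test_merged_ch_equals_pooled_scheme_for_xrays(self, xray):
        # explicit methine fragment pooled at construction vs pre-pooled CH2:
        # identical composition and volume, hence identical X-ray contrast
        merged = default_pc_scheme(n_CH2=28, n_CH=2, n_CH3=2)
        pooled = ParsingScheme(
            components=tuple(
                Component(c.name, dict(c.composition), c.volume_ref, c.role)
                for c in merged.components
            )
        )
        sdp = make_sdp(merged)
        q = np.linspace(0.01, 1.0, 80)
        F1 = form_factor(q, sdp, merged, xray)
        F2 = form_factor(q, sdp, pooled, xray)
        np.testing.assert_allclose(F1, F2, rtol=1e-12)


class TestCholesterolMerging:
    def test_chol_volume_folds_into_ch2(self):
        plain = default_pc_scheme(28, 2, 2)
        chol = default_pc_scheme(28, 2, 2, cholesterol_fraction=0.2)
        sdp_p = make_sdp(plain)
        sdp_c = make_sdp(chol)
        extra = 0.2 / 0.8 * chol.cholesterol_volume
        assert sdp_c.hydrocarbon_volume(chol) == pytest.approx(
            sdp_p.hydrocarbon_volume(plain) + extra
        )

    def test_chol_scheme_increases_ch2_xray_density_denominator(self, xray):
        chol = default_pc_scheme(28, 2, 2, cholesterol_fraction=0.2)
        plain = default_pc_scheme(28, 2, 2)
        rho_c = component_density(chol.ch2, xray, chol)
        rho_p = component_density(plain.ch2, xray, plain)
        assert rho_c != pytest.approx(rho_p)
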