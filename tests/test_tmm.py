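"""Transfer-matrix core: Snell/Fresnel/matrix units and closed-form oracles."""

import numpy as np
import pytest

from tmmdesign import (
    LayerStack,
    SpectralGrid,
    TotalInternalReflectionError,
    default_grid,
    fresnel_interface,
    layer_matrix,
    power_coefficients,
    refraction_angles,
    stack_coefficients,
    stack_matrix,
    transmittance_spectrum,
    transmittance_with_gradient,
)
from tmmdesign.synthetic import make_bandpass_stack

from conftest import random_alternating_stack

BARE_GLASS = LayerStack(1.0, np.empty(0), np.empty(0), 1.52)


# ---------------------------------------------------------------------------
# Oracles, independent of the TMM implementation
# ---------------------------------------------------------------------------


def fresnel_power_oracle(n1, n2, theta1, pol):
    """Closed-form single-interface R and T from Snell + Fresnel arithmetic."""
    theta2 = np.arcsin(n1 * np.sin(theta1) / n2)
    c1, c2 = np.cos(theta1), np.cos(theta2)
    if pol == "s":
        r = (n1 * c1 - n2 * c2) / (n1 * c1 + n2 * c2)
        t = 2 * n1 * c1 / (n1 * c1 + n2 * c2)
    else:
        r = (n2 * c1 - n1 * c2) / (n2 * c1 + n1 * c2)
        t = 2 * n1 * c1 / (n2 * c1 + n1 * c2)
    return r**2, (n2 * c2) / (n1 * c1) * t**2


def airy_single_film_oracle(n0, n1, n2, d, wavelength):
    """Single-film transmittance at normal incidence via the Airy summation."""
    r01 = (n0 - n1) / (n0 + n1)
    r12 = (n1 - n2) / (n1 + n2)
    t01 = 2 * n0 / (n0 + n1)
    t12 = 2 * n1 / (n1 + n2)
    delta = 2 * np.pi * n1 * d / wavelength
    t = t01 * t12 * np.exp(-1j * delta) / (1 + r01 * r12 * np.exp(-2j * delta))
    return (n2 / n0) * abs(t) ** 2


def quarter_wave_admittance_oracle(n0, n_hi, n_lo, n_sub, pairs):
    """(HL)^m quarter-wave reflectance at the design wavelength.

    Each quarter-wave layer transforms the admittance Y → n²/Y; applying
    the stack from substrate to air gives Y = (n_hi/n_lo)^{2m}·n_sub and
    R = ((n0 − Y)/(n0 + Y))².
    """
    y = n_sub
    for _ in range(pairs):
        y = n_lo**2 / y
        y = n_hi**2 / y
    return ((n0 - y) / (n0 + y)) ** 2


# ---------------------------------------------------------------------------
# refraction_angles
# ---------------------------------------------------------------------------


class TestRefractionAngles:
    def test_normal_incidence_all_zero(self):
        stack = LayerStack(1.0, [2.3, 1.46], [100, 100], 1.52)
        assert np.allclose(refraction_angles(stack, 0.0), 0.0)

    def test_substrate_angle_closed_form(self):
        theta0 = np.deg2rad(20)
        angles = refraction_angles(BARE_GLASS, theta0)
        assert angles[-1] == pytest.approx(np.arcsin(np.sin(theta0) / 1.52), abs=1e-14)

    def test_substrate_angle_independent_of_inner_layers(self):
        theta0 = np.deg2rad(35)
        with_layers = LayerStack(1.0, [2.3, 1.46, 2.3], [50, 80, 120], 1.52)
        a1 = refraction_angles(BARE_GLASS, theta0)[-1]
        a2 = refraction_angles(with_layers, theta0)[-1]
        assert a1 == pytest.approx(a2, abs=1e-15)

    def test_snell_invariant_conserved(self, stack10):
        theta0 = np.deg2rad(40)
        angles = refraction_angles(stack10, theta0)
        n = stack10.all_indices()
        assert np.allclose(n * np.sin(angles), np.sin(theta0), atol=1e-14)

    def test_total_internal_reflection_detected(self):
        # dense injection medium into air-like substrate beyond the critical angle
        stack = LayerStack(1.52, np.empty(0), np.empty(0), 1.0)
        with pytest.raises(TotalInternalReflectionError):
            refraction_angles(stack, np.deg2rad(60))

    def test_invalid_incidence_rejected(self):
        with pytest.raises(ValueError):
            refraction_angles(BARE_GLASS, np.pi / 2)


# ---------------------------------------------------------------------------
# fresnel_interface
# ---------------------------------------------------------------------------


class TestFresnelInterface:
    @pytest.mark.parametrize("pol", ["s", "p"])
    def test_no_interface(self, pol):
        r, t = fresnel_interface(1.5, 1.5, 0.3, 0.3, pol)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert t == pytest.approx(1.0, abs=1e-15)

    def test_air_glass_normal_incidence(self):
        r, t = fresnel_interface(1.0, 1.5, 0.0, 0.0, "s")
        assert r == pytest.approx(-0.2, abs=1e-15)
        assert r**2 == pytest.approx(0.04, abs=1e-15)

    def test_brewster_angle_kills_p_reflection(self):
        n1, n2 = 1.0, 1.52
        theta_b = np.arctan(n2 / n1)
        theta2 = np.arcsin(n1 * np.sin(theta_b) / n2)
        r_p, _ = fresnel_interface(n1, n2, theta_b, theta2, "p")
        assert abs(r_p) < 1e-12

    @pytest.mark.parametrize("pol", ["s", "p"])
    @pytest.mark.parametrize("n2,theta_deg", [(1.52, 0), (2.3, 20), (1.46, 55)])
    def test_interface_energy_conservation(self, pol, n2, theta_deg):
        n1, theta1 = 1.0, np.deg2rad(theta_deg)
        theta2 = np.arcsin(n1 * np.sin(theta1) / n2)
        r, t = fresnel_interface(n1, n2, theta1, theta2, pol)
        T = (n2 * np.cos(theta2)) / (n1 * np.cos(theta1)) * t**2
        assert r**2 + T == pytest.approx(1.0, abs=1e-12)

    def test_unknown_polarization_rejected(self):
        with pytest.raises(ValueError):
            fresnel_interface(1.0, 1.5, 0.0, 0.0, "x")


# ---------------------------------------------------------------------------
# layer_matrix / stack_matrix / stack_coefficients / power_coefficients
# ---------------------------------------------------------------------------


class TestMatrices:
    def test_trivial_layer_is_identity(self):
        assert np.allclose(layer_matrix(0.0, 0.0, 1.0), np.eye(2))

    def test_quarter_phase(self):
        m = layer_matrix(np.pi / 2, 0.0, 1.0)
        assert np.allclose(m, np.diag([-1j, 1j]))

    def test_zero_transmission_rejected(self):
        with pytest.raises(ZeroDivisionError):
            layer_matrix(0.1, 0.5, 0.0)

    @pytest.mark.parametrize("theta_deg", [0, 25])
    def test_single_interface_determinant(self, theta_deg):
        # det M = (1 - r²)/t² = n2 cosθ2 / (n1 cosθ1) for s-polarization
        n1, n2 = 1.0, 2.3
        theta1 = np.deg2rad(theta_deg)
        theta2 = np.arcsin(n1 * np.sin(theta1) / n2)
        r, t = fresnel_interface(n1, n2, theta1, theta2, "s")
        m = layer_matrix(0.0, r, t)
        expected = n2 * np.cos(theta2) / (n1 * np.cos(theta1))
        assert np.linalg.det(m) == pytest.approx(expected, abs=1e-12)

    def test_empty_stack_same_media_is_identity(self):
        stack = LayerStack(1.52, np.empty(0), np.empty(0), 1.52)
        m = stack_matrix(stack, 0.0, 550.0, "s")
        assert np.allclose(m, np.eye(2), atol=1e-15)

    @pytest.mark.parametrize("pol", ["s", "p"])
    def test_bare_interface_matches_fresnel(self, pol):
        theta0 = np.deg2rad(30)
        m = stack_matrix(BARE_GLASS, theta0, 550.0, pol)
        r, t = stack_coefficients(m)
        theta_sub = np.arcsin(np.sin(theta0) / 1.52)
        r_ref, t_ref = fresnel_interface(1.0, 1.52, theta0, theta_sub, pol)
        assert r == pytest.approx(r_ref, abs=1e-14)
        assert t == pytest.approx(t_ref, abs=1e-14)

    def test_inert_zero_thickness_layer_changes_nothing(self):
        base = LayerStack(1.0, [2.3], [120.0], 1.52)
        padded = LayerStack(1.0, [2.3, 1.52], [120.0, 0.0], 1.52)
        m1 = stack_matrix(base, 0.2, 600.0, "p")
        m2 = stack_matrix(padded, 0.2, 600.0, "p")
        assert np.allclose(m1, m2, atol=1e-13)

    def test_identity_matrix_coefficients(self):
        r, t = stack_coefficients(np.eye(2, dtype=complex))
        assert (r, t) == (0.0, 1.0)

    def test_air_glass_amplitude_reflection(self):
        r, _ = stack_coefficients(stack_matrix(BARE_GLASS, 0.0, 550.0, "s"))
        assert r == pytest.approx((1 - 1.52) / (1 + 1.52), abs=1e-14)

    def test_fabry_perot_resonance_transmits_fully(self):
        # symmetric lossless etalon between identical media at a half-wave resonance
        etalon = LayerStack(1.0, [2.0], [550.0 / (2 * 2.0)], 1.0)
        m = stack_matrix(etalon, 0.0, 550.0, "s")
        r, t = stack_coefficients(m)
        _, T = power_coefficients(r, t, etalon, 0.0, 0.0)
        assert T == pytest.approx(1.0, abs=1e-12)

    def test_air_glass_power_transmittance(self):
        m = stack_matrix(BARE_GLASS, 0.0, 550.0, "s")
        r, t = stack_coefficients(m)
        R, T = power_coefficients(r, t, BARE_GLASS, 0.0, 0.0)
        assert T == pytest.approx(4 * 1.52 / 2.52**2, abs=1e-14)
        assert R + T == pytest.approx(1.0, abs=1e-14)


# ---------------------------------------------------------------------------
# transmittance_spectrum (vectorized path)
# ---------------------------------------------------------------------------


class TestSpectrum:
    @pytest.mark.parametrize("theta_deg", [0, 20, 40])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_energy_conservation(self, grid, theta_deg, seed):
        stack = random_alternating_stack(20, seed)
        sr = transmittance_spectrum(stack, np.deg2rad(theta_deg), grid)
        assert np.all(np.abs(sr.R_s + sr.T_s - 1) < 1e-9)
        assert np.all(np.abs(sr.R_p + sr.T_p - 1) < 1e-9)
        for arr in (sr.T_s, sr.T_p, sr.R_s, sr.R_p):
            assert np.all((arr >= -1e-12) & (arr <= 1 + 1e-12))

    def test_normal_incidence_polarization_degeneracy(self, grid, stack10):
        sr = transmittance_spectrum(stack10, 0.0, grid)
        assert np.max(np.abs(sr.T_s - sr.T_p)) < 1e-12

    def test_empty_stack_equals_bare_interface(self, grid):
        sr = transmittance_spectrum(BARE_GLASS, 0.0, grid)
        assert np.allclose(sr.T_s, 4 * 1.52 / 2.52**2, atol=1e-12)

    def test_single_film_matches_airy_oracle(self):
        film = LayerStack(1.0, [2.3], [137.0], 1.52)
        grid = SpectralGrid(np.linspace(400, 800, 401))
        sr = transmittance_spectrum(film, 0.0, grid)
        oracle = np.array(
            [airy_single_film_oracle(1.0, 2.3, 1.52, 137.0, w) for w in grid.wavelengths]
        )
        assert np.allclose(sr.T_s, oracle, atol=1e-12)

    def test_quarter_wave_stack_matches_admittance_oracle(self):
        lam = 550.0
        pairs = 5
        stack = random_alternating_stack(2 * pairs, seed=0)
        d = np.where(np.arange(2 * pairs) % 2 == 0, lam / (4 * 2.3), lam / (4 * 1.46))
        stack = stack.with_thicknesses(d)
        sr = transmittance_spectrum(stack, 0.0, SpectralGrid(np.array([lam])))
        expected = quarter_wave_admittance_oracle(1.0, 2.3, 1.46, 1.52, pairs)
        assert sr.R_s[0] == pytest.approx(expected, abs=1e-8)

    def test_bandpass_peak_blue_shifts_at_oblique_incidence(self):
        stack = make_bandpass_stack(mirror_pairs=4, lambda_ref=550.0)
        fine = SpectralGrid(np.linspace(480, 620, 1401))
        peak0 = fine.wavelengths[np.argmax(transmittance_spectrum(stack, 0.0, fine).T_unpolarized)]
        peak20 = fine.wavelengths[
            np.argmax(transmittance_spectrum(stack, np.deg2rad(20), fine).T_unpolarized)
        ]
        assert peak20 < peak0

    @pytest.mark.parametrize("pol", ["s", "p"])
    def test_gradient_matches_finite_differences(self, grid, stack10, pol):
        theta = np.deg2rad(20)
        T, dT = transmittance_with_gradient(stack10, theta, grid, pol)
        assert np.allclose(T, getattr(transmittance_spectrum(stack10, theta, grid), f"T_{pol}"))
        h = 1e-3
        for m in range(stack10.num_layers):
            up = stack10.thicknesses.copy()
            dn = stack10.thicknesses.copy()
            up[m] += h
            dn[m] -= h
            sp = getattr(transmittance_spectrum(stack10.with_thicknesses(up), theta, grid), f"T_{pol}")
            sm = getattr(transmittance_spectrum(stack10.with_thicknesses(dn), theta, grid), f"T_{pol}")
            fd = (sp - sm) / (2 * h)
            rel = np.abs(dT[m] - fd) / np.maximum(np.abs(fd), 1e-8)
            assert rel.max() < 1e-5


class TestSpectrumProperties:
    """Seeded-random property checks over the stack/angle space."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        num_layers=st.integers(1, 30),
        seed=st.integers(0, 10_000),
        theta_deg=st.floats(0.0, 60.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_energy_conserved_and_snell_invariant(self, num_layers, seed, theta_deg):
        stack = random_alternating_stack(num_layers, seed)
        theta = np.deg2rad(theta_deg)
        small = SpectralGrid(np.linspace(400.0, 800.0, 21))
        sr = transmittance_spectrum(stack, theta, small)
        assert np.max(np.abs(sr.R_s + sr.T_s - 1)) < 1e-9
        assert np.max(np.abs(sr.R_p + sr.T_p - 1)) < 1e-9
        angles = refraction_angles(stack, theta)
        assert np.allclose(stack.all_indices() * np.sin(angles), np.sin(theta), atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_unpolarized_transmittance_within_polarized_envelope(self, seed):
        stack = random_alternating_stack(8, seed)
        small = SpectralGrid(np.linspace(400.0, 800.0, 21))
        sr = transmittance_spectrum(stack, np.deg2rad(20), small)
        mean = (sr.T_s + sr.T_p) / 2
        assert np.all(mean <= np.maximum(sr.T_s, sr.T_p) + 1e-14)
        assert np.all(mean >= np.minimum(sr.T_s, sr.T_p) - 1e-14)


class TestLayerStackValidation:
    def test_index_below_one_rejected(self):
        with pytest.raises(ValueError):
            LayerStack(1.0, [0.9], [100.0], 1.52)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            LayerStack(1.0, [2.3], [-1.0], 1.52)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            LayerStack(1.0, [2.3, 1.46], [100.0], 1.52)
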