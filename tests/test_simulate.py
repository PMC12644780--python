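"""Forward models: dispersion elements, the analytic Cole-Cole distribution,
cell-scale time constants and the synthetic-spectrum generators."""

import math

import numpy as np
import pytest

import tissuedrt as td
from tissuedrt.core import RelaxationGrid, ValidationError
from tissuedrt.simulate import (
    BOLTZMANN,
    CellModel,
    DispersionElement,
    cole_cole_density,
    element_impedance,
)


class TestElements:
    @pytest.mark.parametrize(
        "element",
        [
            DispersionElement("debye", 500.0, {"tau0": 1e-4}),
            DispersionElement("rq", 800.0, {"q": 0.8, "Q": 3e-4}),
            DispersionElement("lognormal", 300.0, {"mu": 1e-5, "sigma": 0.5}),
            DispersionElement("warburg_finite", 900.0, {"tau_d": 0.5}),
        ],
        ids=["debye", "rq", "lognormal", "warburg"],
    )
    def test_dc_limit_is_r_and_high_frequency_limit_vanishes(self, element):
        z0 = element_impedance(element, np.array([0.0]))[0]
        z_inf = element_impedance(element, np.array([1e12]))[0]
        assert z0 == pytest.approx(element.R, rel=1e-9)
        assert abs(z_inf) < 1e-3 * element.R

    def test_rq_with_unit_exponent_reduces_to_debye(self, frequencies):
        tau0 = 2e-4
        rq = DispersionElement("rq", 750.0, {"q": 1.0, "Q": tau0 / 750.0})
        debye = DispersionElement("debye", 750.0, {"tau0": tau0})
        z1 = element_impedance(rq, frequencies)
        z2 = element_impedance(debye, frequencies)
        assert np.abs(z1 - z2).max() < 1e-12 * 750.0

    def test_narrow_lognormal_approaches_debye(self, frequencies):
        ln = DispersionElement("lognormal", 400.0, {"mu": 1e-5, "sigma": 0.01})
        de = DispersionElement("debye", 400.0, {"tau0": 1e-5})
        z1 = element_impedance(ln, frequencies)
        z2 = element_impedance(de, frequencies)
        assert (np.abs(z1 - z2) / np.abs(z2)).max() < 1e-3

    def test_lognormal_matches_dense_trapezoid_quadrature(self, frequencies):
        mu, sigma, R = 3e-5, 0.6, 500.0
        el = DispersionElement("lognormal", R, {"mu": mu, "sigma": sigma})
        z = element_impedance(el, frequencies)
        x = np.linspace(math.log(mu) - 10 * sigma, math.log(mu) + 10 * sigma, 100_000)
        pdf = np.exp(-((x - math.log(mu)) ** 2) / (2 * sigma**2)) / (
            sigma * math.sqrt(2 * math.pi)
        )
        kern = 1.0 / (1.0 + 1j * 2 * np.pi * frequencies[:, None] * np.exp(x)[None, :])
        z_ref = R * np.trapezoid(pdf[None, :] * kern, x, axis=1)
        assert (np.abs(z - z_ref) / np.abs(z_ref)).max() < 1e-6


class TestColeColeDistribution:
    def test_symmetric_about_characteristic_time(self):
        x0 = math.log(1e-4)
        delta = np.linspace(0.1, 4.0, 20)
        left = cole_cole_density(x0 - delta, x0, 0.8)
        right = cole_cole_density(x0 + delta, x0, 0.8)
        np.testing.assert_allclose(left, right, rtol=1e-12)

    def test_unit_normalization(self):
        x0 = 0.0
        x = np.linspace(-60, 60, 200_001)
        area = np.trapezoid(cole_cole_density(x, x0, 0.8), x)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_forward_integral_reproduces_rq_impedance(self, frequencies):
        """Mandated pre-build validation: pushing the closed-form distribution
        through the relaxation integral reproduces the RQ element's impedance
        within 0.1% across the whole acquisition band."""
        el = DispersionElement.rq_from_tau(1000.0, 1e-4, 0.8)
        x0 = math.log(el.tau_char)
        x = np.linspace(x0 - 45, x0 + 45, 9001)
        g = cole_cole_density(x, x0, 0.8)
        kern = 1.0 / (1.0 + 1j * 2 * np.pi * frequencies[:, None] * np.exp(x)[None, :])
        z_forward = el.R * np.trapezoid(g[None, :] * kern, x, axis=1)
        z_direct = element_impedance(el, frequencies)
        assert (np.abs(z_forward - z_direct) / np.abs(z_direct)).max() < 1e-3

    def test_sampled_drt_carries_elements_resistance(self, grid):
        el = DispersionElement.rq_from_tau(1000.0, 1e-4, 0.8)
        drt = td.cole_cole_drt(el, grid)
        assert drt.R_p == pytest.approx(1000.0, rel=0.01)

    def test_degenerate_exponent_rejected(self, grid):
        el = DispersionElement("rq", 100.0, {"q": 1.0, "Q": 1e-6})
        with pytest.raises(ValidationError, match="debye"):
            td.cole_cole_drt(el, grid)


class TestCellTimeConstants:
    def test_membrane_polarization_hand_value(self):
        # r=50 um, C_m=1e-2 F/m^2, sigma_c=0.5, sigma_0=0.1 S/m
        # tau = 5e-5 * 1e-2 * (2 + 5) = 3.5e-6 s
        cell = CellModel(r_cell=50e-6, C_m=1e-2, sigma_c=0.5, sigma_0=0.1)
        assert td.beta_time_constant(cell) == pytest.approx(3.5e-6, rel=1e-12)

    def test_counterion_time_constant_formula(self):
        cell = CellModel(r_cell=50e-6, u=5e-8, T=300.0)
        expected = (50e-6) ** 2 / (2 * 5e-8 * BOLTZMANN * 300.0)
        assert td.alpha_time_constant(cell) == pytest.approx(expected, rel=1e-12)

    def test_series_capacitance_limits(self):
        stiff = CellModel(C_m=1e-2, C_dl=1e4)
        assert td.series_membrane_capacitance(stiff) == pytest.approx(1e-2, rel=1e-5)
        equal = CellModel(C_m=1e-2, C_dl=1e-2)
        assert td.series_membrane_capacitance(equal) == pytest.approx(5e-3, rel=1e-12)

    def test_double_layer_shortens_beta_time_constant(self):
        cell = CellModel(C_m=1e-2, C_dl=2e-2)
        assert td.beta_time_constant(cell, include_double_layer=True) < td.beta_time_constant(cell)


class TestStarchConductivity:
    def test_no_inclusions_is_identity(self):
        assert td.starch_effective_conductivity(0.5, 0.0) == 0.5

    def test_three_quarters_loading(self):
        # (1 - 0.75) / (1 + 0.375) = 2/11 of the bare conductivity
        assert td.starch_effective_conductivity(1.0, 0.75) == pytest.approx(
            0.25 / 1.375, rel=1e-12
        )

    def test_strictly_decreasing_in_loading(self):
        ps = np.linspace(0.0, 0.95, 30)
        vals = [td.starch_effective_conductivity(0.5, p) for p in ps]
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))

    def test_starch_loading_multiplies_beta_time_constant_about_fivefold(self):
        """At 75% starch loading the membrane polarization time constant grows
        by a factor of a few (the dilution of cytoplasm conductivity)."""
        lean = CellModel(sigma_c=0.5, sigma_0=0.5, starch_fraction=0.0)
        loaded = CellModel(sigma_c=0.5, sigma_0=0.5, starch_fraction=0.75)
        ratio = td.beta_time_constant(loaded, include_starch=True) / td.beta_time_constant(
            lean, include_starch=True
        )
        assert 3.0 < ratio < 7.0

    def test_full_packing_rejected(self):
        with pytest.raises(ValidationError):
            td.starch_effective_conductivity(0.5, 1.0)


class TestGenerateSpectrum:
    def test_noiseless_spectrum_is_deterministic_sum(self, frequencies):
        model = td.potato_model(noise_sigma=0.0)
        spec = td.generate_spectrum(model, frequencies)
        z = np.full(frequencies.size, model.R_inf, complex)
        for el in model.elements:
            z += element_impedance(el, frequencies)
        np.testing.assert_allclose(spec.impedance, z, rtol=1e-14)

    def test_same_seed_reproduces_spectrum(self):
        model = td.potato_model(noise_sigma=0.005, seed=42)
        a = td.generate_spectrum(model)
        b = td.generate_spectrum(model)
        np.testing.assert_array_equal(a.impedance, b.impedance)

    def test_different_seeds_differ(self):
        model = td.potato_model(noise_sigma=0.005, seed=42)
        a = td.generate_spectrum(model, seed=1)
        b = td.generate_spectrum(model, seed=2)
        assert np.any(a.impedance != b.impedance)


class TestEpDataset:
    def test_replicates_times_levels_pairs(self):
        model = td.potato_model(noise_sigma=0.005, seed=0)
        levels = [60.0, 100.0, 200.0, 300.0, 400.0, 500.0, 750.0, 1000.0]
        profile = {lv: td.reversible_profile() for lv in levels}
        recs = td.generate_ep_dataset(model, levels, 3, profile, seed=0)
        assert len(recs) == 24

    def test_null_profile_changes_only_the_noise_draw(self, frequencies):
        model = td.potato_model(noise_sigma=0.0, seed=0)
        recs = td.generate_ep_dataset(
            model, [100.0], 1, {100.0: td.EffectProfile()}, seed=0, jitter_cv=0.0,
            frequencies=frequencies,
        )
        np.testing.assert_allclose(
            recs[0].pre.impedance, recs[0].post.impedance, rtol=1e-12
        )

    def test_reversible_profile_preserves_dc_resistance_exactly(self):
        model = td.potato_model(noise_sigma=0.0, seed=0)
        recs = td.generate_ep_dataset(
            model, [100.0], 1, {100.0: td.reversible_profile()}, seed=0
        )
        pre_r0 = sum(v["R"] for v in recs[0].truth_pre.values())
        post_r0 = sum(v["R"] for v in recs[0].truth_post.values())
        assert post_r0 == pytest.approx(pre_r0, rel=1e-12)
        # but the membrane time constants moved
        assert recs[0].truth_post["beta_large"]["mu"] != recs[0].truth_pre["beta_large"]["mu"]

    def test_missing_level_in_profile_rejected(self):
        model = td.potato_model()
        with pytest.raises(ValidationError, match="missing"):
            td.generate_ep_dataset(model, [60.0, 100.0], 1, {60.0: td.EffectProfile()})
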