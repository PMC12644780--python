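"""Gaussian decomposition, DC-resistance identities and F-test selection."""

import math

import numpy as np
import pytest
import scipy.integrate

import tissuedrt as td
from tissuedrt.core import DRTResult, GaussianComponent, ValidationError
from tissuedrt.decompose import f_test

from conftest import SQRT_2PI, gaussian_curve_drt


class TestFitGaussians:
    def test_single_component_self_fit(self, grid):
        drt = gaussian_curve_drt([(300.0, 1e-5, 0.5)], grid)
        m = td.fit_gaussians(drt, 1, seed=0)
        c = m.components[0]
        assert c.a == pytest.approx(300.0, rel=0.005)
        assert c.mu == pytest.approx(1e-5, rel=0.005)
        assert c.sigma == pytest.approx(0.5, rel=0.005)

    def test_two_separated_components_ordered_by_mu(self, grid):
        truth = [(200.0, 1e-6, 0.4), (350.0, 1e-4, 0.4)]
        m = td.fit_gaussians(gaussian_curve_drt(truth, grid), 2, seed=0)
        slow, fast = m.components
        assert slow.mu == pytest.approx(1e-4, rel=0.02)
        assert slow.a == pytest.approx(350.0, rel=0.02)
        assert fast.mu == pytest.approx(1e-6, rel=0.02)
        assert fast.a == pytest.approx(200.0, rel=0.02)

    def test_zero_curve_rejected(self, grid):
        drt = DRTResult(grid, np.zeros(grid.M), 0.0)
        with pytest.raises(ValidationError, match="no mass"):
            td.fit_gaussians(drt, 1, seed=0)

    def test_k_too_large_for_window_rejected(self, grid):
        drt = gaussian_curve_drt([(300.0, 1e-5, 0.5)], grid)
        with pytest.raises(ValidationError, match="bins"):
            td.fit_gaussians(drt, 3, tau_window=(5e-6, 1.2e-5), seed=0)

    def test_six_component_recovery_when_separated(self, grid):
        """Components >= 0.5 natural-log units apart are each recovered
        within x/1.25 in location and 10% in DC contribution."""
        truth = [
            (39 / (0.4 * SQRT_2PI), 3e-4, 0.4),
            (221 / (0.4 * SQRT_2PI), 2e-5, 0.4),
            (270 / (0.4 * SQRT_2PI), 6e-6, 0.4),
            (266 / (0.4 * SQRT_2PI), 2e-6, 0.4),
            (139 / (0.3 * SQRT_2PI), 4e-7, 0.3),
            (26 / (0.25 * SQRT_2PI), 1.5e-7, 0.25),
        ]
        drt = gaussian_curve_drt(truth, grid, seed=11, noise_frac=0.01, R_inf=150.0)
        m = td.fit_gaussians(drt, 6, seed=0)
        for c, (a, mu, s) in zip(m.components, truth):
            assert 1 / 1.25 < c.mu / mu < 1.25
            assert c.R_pk == pytest.approx(a * s * SQRT_2PI, rel=0.10)


class TestComponentResistances:
    def test_unit_case(self):
        c = GaussianComponent(1.0, 1e-5, 1.0)
        assert c.R_pk == pytest.approx(2.5066, abs=5e-5)

    @pytest.mark.parametrize("a,sigma", [(2.0, 0.5), (10.0, 0.15), (1.0, 1.8)])
    def test_area_identity_matches_lognormal_quadrature(self, a, sigma):
        """The closed-form area a*sigma*sqrt(2pi) equals the integral of the
        log-normal density (a/tau') exp(-(ln(tau'/mu))^2 / (2 sigma^2)) dtau'
        restated per unit natural-log time."""
        mu = 3e-5
        val, _ = scipy.integrate.quad(
            lambda tau: (a / tau) * math.exp(-((math.log(tau / mu)) ** 2) / (2 * sigma**2)),
            mu * math.exp(-8 * sigma),
            mu * math.exp(8 * sigma),
            points=[mu * math.exp(-2 * sigma), mu, mu * math.exp(2 * sigma)],
            limit=500,
        )
        c = GaussianComponent(a, mu, sigma)
        assert c.R_pk == pytest.approx(val, rel=1e-6)

    def test_r0_additivity_against_frequency_domain_dc_limit(self, grid):
        """R_inf + sum R_pk equals the omega->0 limit of the mixture's
        impedance computed by quadrature of the relaxation integral."""
        comps = [GaussianComponent(120.0, 1e-5, 0.5), GaussianComponent(80.0, 1e-3, 0.3)]
        model = td.DecompositionModel(comps, R_inf=100.0)
        z0 = 0.0
        for c in comps:
            val, _ = scipy.integrate.quad(
                lambda x, c=c: c.a * math.exp(-((x - math.log(c.mu)) ** 2) / (2 * c.sigma**2)),
                math.log(c.mu) - 10 * c.sigma,
                math.log(c.mu) + 10 * c.sigma,
            )
            z0 += val
        assert model.R_0 == pytest.approx(100.0 + z0, rel=0.005)

    def test_component_resistances_returns_model_values(self):
        m = td.DecompositionModel(
            [GaussianComponent(5.0, 1e-4, 0.4), GaussianComponent(3.0, 1e-6, 0.2)],
            R_inf=10.0,
        )
        r_pks, r0 = td.decompose.component_resistances(m)
        assert r0 == pytest.approx(10.0 + r_pks.sum(), rel=1e-12)


class TestFTest:
    def test_printed_formula_arithmetic(self):
        # rss 10 -> 5 at n=120, k=5: F = (5/5) * (120-16)/3 = 104/3
        rep = f_test(10.0, 5.0, 120, 5)
        assert rep.F == pytest.approx(104 / 3, rel=1e-12)
        assert rep.df1 == 3 and rep.df2 == 104

    def test_no_improvement_gives_f_zero_p_one(self):
        rep = f_test(5.0, 5.0, 120, 5)
        assert rep.F == 0.0
        assert rep.p_value == pytest.approx(1.0)

    def test_perfect_fit_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            f_test(1.0, 0.0, 120, 5)

    def test_insufficient_degrees_of_freedom_rejected(self):
        with pytest.raises(ValidationError):
            f_test(10.0, 5.0, 10, 3)  # df2 = 0

    def test_p_value_is_upper_tail_probability(self):
        rep = f_test(10.0, 5.0, 22, 3)  # F = 12/3 * ... whatever it is
        import scipy.stats

        assert rep.p_value == pytest.approx(
            scipy.stats.f.sf(rep.F, rep.df1, rep.df2), rel=1e-12
        )


class TestSelectK:
    def test_single_component_truth_chooses_one(self, grid):
        drt = gaussian_curve_drt([(300.0, 1e-5, 0.4)], grid, seed=5, noise_frac=0.01)
        res = td.select_K(drt, (1, 3), 0.05, tau_window=(2e-6, 5e-5), seed=5)
        assert res.chosen_K == 1

    def test_rss_non_increasing_in_k(self, grid):
        truth = [(300.0, 1e-5, 0.4), (150.0, 3e-4, 0.35)]
        drt = gaussian_curve_drt(truth, grid, seed=2, noise_frac=0.01)
        res = td.select_K(drt, (1, 4), 0.05, tau_window=(2e-6, 1.5e-3), seed=2)
        rss = [res.models[k].rss for k in sorted(res.models)]
        assert all(r1 >= r2 - 1e-9 for r1, r2 in zip(rss, rss[1:]))

    def test_empty_tail_window_rejected(self, grid):
        drt = gaussian_curve_drt([(300.0, 1e-5, 0.4)], grid)
        with pytest.raises(ValidationError, match="tail"):
            td.select_K(drt, (1, 3), 0.05, tail_cutoff=1e-8)

    def test_tail_reports_use_tail_bin_count(self, grid):
        truth = [(300.0, 1e-5, 0.4), (150.0, 2e-6, 0.35)]
        drt = gaussian_curve_drt(truth, grid, seed=4, noise_frac=0.01)
        res = td.select_K(
            drt, (1, 3), 0.05, tail_cutoff=6e-6, tau_window=(4e-7, 1e-4), seed=4
        )
        n_tail = int(((drt.grid.centers >= 4e-7) & (drt.grid.centers < 6e-6)).sum())
        assert res.tail_reports
        for rep in res.tail_reports:
            assert rep.df2 == n_tail - 3 * rep.k - 1
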