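"""Forward-model unit tests against independent oracles (quadrature,
direct summation, Monte-Carlo sampling and closed forms)."""

import numpy as np
import pytest
from scipy import integrate

from vesifit import forward
from vesifit.errors import ParameterDomainError
from vesifit.models import (
    BilayerParams,
    LamellarOrganization,
    MixtureComponent,
    MixtureModel,
    SchulzSizeDistribution,
)

from conftest import random_bilayers


class TestSchulzDensity:
    def test_normalization(self, schulz_50_5):
        total, _ = integrate.quad(
            lambda r: forward.schulz_density(r, schulz_50_5), 0, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mean(self, schulz_50_5):
        # the validation-case distribution: mean 50 nm, 10% polydispersity
        m1, _ = integrate.quad(
            lambda r: r * forward.schulz_density(r, schulz_50_5), 0, np.inf
        )
        assert m1 == pytest.approx(50.0, abs=1e-6)

    def test_std_via_quadrature_oracle(self, schulz_50_5):
        m1, _ = integrate.quad(
            lambda r: r * forward.schulz_density(r, schulz_50_5), 0, 300
        )
        m2, _ = integrate.quad(
            lambda r: r**2 * forward.schulz_density(r, schulz_50_5), 0, 300
        )
        assert np.sqrt(m2 - m1**2) == pytest.approx(5.0, abs=1e-6)

    def test_non_negative(self, schulz_50_5):
        r = np.linspace(0, 200, 500)
        assert np.all(forward.schulz_density(r, schulz_50_5) >= 0)

    def test_negative_radius_rejected(self, schulz_50_5):
        with pytest.raises(ParameterDomainError):
            forward.schulz_density(-1.0, schulz_50_5)


class TestThinShellFormFactor:
    def test_low_s_limit(self):
        # sin(sr)/(sr) -> 1, so F -> r^2
        assert forward.thin_shell_form_factor(1e-9, 50.0) == pytest.approx(2500.0)

    def test_first_zero(self):
        # first zero of sin(sr) at s = pi / r
        s0 = np.pi / 50.0
        assert s0 == pytest.approx(0.06283, abs=1e-5)
        assert forward.thin_shell_form_factor(s0, 50.0) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form(self):
        s, r = 0.1, 50.0
        expected = (r**2 * np.sin(s * r) / (s * r)) ** 2
        assert float(forward.thin_shell_form_factor(s, r) ** 2) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ParameterDomainError):
            forward.thin_shell_form_factor(-0.1, 50.0)
        with pytest.raises(ParameterDomainError):
            forward.thin_shell_form_factor(0.1, 0.0)


class TestBilayerDensity:
    def test_mirror_symmetry(self, symmetric_bilayer):
        z = np.linspace(-5, 5, 201)
        rho = forward.bilayer_density(z, symmetric_bilayer)
        assert rho == pytest.approx(rho[::-1], rel=1e-12)

    def test_asymmetric_profile_still_even(self, dmpc30_bilayer):
        # mirrored pairs keep rho even even with two distinct headgroup bands
        z = np.linspace(-5, 5, 201)
        rho = forward.bilayer_density(z, dmpc30_bilayer)
        assert rho == pytest.approx(rho[::-1], rel=1e-12)

    def test_centre_value_closed_form(self, symmetric_bilayer):
        # rho(0) = -rho_r + headgroup tails; tails are exp(-z_H^2/2 sigma_H^2) ~ 1e-22
        expected = -1.5 + 4.0 * np.exp(-(2.0**2) / (2 * 0.2**2))
        assert float(forward.bilayer_density(0.0, symmetric_bilayer)) == pytest.approx(expected)

    def test_headgroup_band_position(self, dmpc30_bilayer):
        # the positive band maximum sits between the two headgroup centres
        z = np.linspace(0, 4, 8001)
        rho = forward.bilayer_density(z, dmpc30_bilayer)
        z_max = z[np.argmax(rho)]
        assert 1.5 < z_max < 2.0


class TestBilayerFormFactor:
    @pytest.mark.parametrize("p", random_bilayers(20, seed=42))
    def test_fourier_quadrature_oracle(self, p):
        s_values = [0.05, 0.5, 1.0, 2.5]
        for s in s_values:
            num, _ = integrate.quad(
                lambda z: forward.bilayer_density(z, p) * np.cos(s * z),
                -10.0, 10.0, limit=200, epsabs=1e-12, epsrel=1e-10,
            )
            ana = float(forward.bilayer_form_factor(s, p))
            assert ana == pytest.approx(num, rel=1e-6, abs=1e-9)

    def test_zero_s_closed_form(self, dmpc30_bilayer):
        p = dmpc30_bilayer
        expected = np.sqrt(2 * np.pi) * (
            2 * p.sigma_H1 + 2 * p.A2_over_A1 * p.sigma_H2 - p.rho_r * p.sigma_C
        )
        assert float(forward.bilayer_form_factor(0.0, p)) == pytest.approx(expected)

    def test_single_pair_zeros(self):
        # with a vanishing central term, zeros track the cos(s z_H) factor
        p = BilayerParams(z_H1=2.0, sigma_H1=0.2, A2_over_A1=1.0,
                          z_H2=2.0, sigma_H2=0.2, rho_r=1e-12, sigma_C=0.4)
        s0 = np.pi / (2 * 2.0)  # first zero of cos(s z_H)
        num, _ = integrate.quad(
            lambda z: forward.bilayer_density(z, p) * np.cos(s0 * z), -10, 10,
            limit=200,
        )
        assert float(forward.bilayer_form_factor(s0, p)) == pytest.approx(0.0, abs=1e-10)
        assert num == pytest.approx(0.0, abs=1e-8)


class TestMCTStructureFactor:
    def test_single_bilayer_is_unity(self):
        lam = LamellarOrganization.suv()
        s = np.geomspace(0.01, 7, 100)
        assert forward.mct_structure_factor(s, lam, 1) == pytest.approx(np.ones(100))

    @pytest.mark.parametrize("L", [2, 3, 5, 7, 10])
    def test_eta_zero_is_laue(self, L):
        lam = LamellarOrganization(
            states=tuple((1.0 / L, i) for i in range(1, L + 1)), d=6.5, eta=0.0
        )
        s = np.linspace(0.05, 3.0, 400)
        S = forward.mct_structure_factor(s, lam, L)
        # direct-summation oracle
        direct = L + 2 * sum((L - m) * np.cos(m * s * 6.5) for m in range(1, L))
        assert S == pytest.approx(direct, rel=1e-12)
        # closed-form Laue function away from sd = 2 pi n
        x = s * 6.5 / 2
        safe = np.abs(np.sin(x)) > 1e-3
        laue = np.sin(L * x[safe]) ** 2 / np.sin(x[safe]) ** 2
        assert S[safe] == pytest.approx(laue, rel=1e-8)

    @pytest.mark.parametrize("L", [1, 2, 7])
    def test_low_s_limit_L_squared(self, L):
        lam = LamellarOrganization(
            states=((1.0, L),) if L > 1 else ((1.0, 1),),
            d=6.5 if L > 1 else 0.0, eta=0.1 if L > 1 else 0.0,
        )
        S = forward.mct_structure_factor(np.array([1e-6]), lam, L)
        assert float(S[0]) == pytest.approx(L**2, rel=1e-6)

    @pytest.mark.parametrize("L,eta", [(5, 0.05), (7, 0.10), (10, 0.15)])
    def test_bragg_peak_position(self, L, eta):
        d = 6.5
        lam = LamellarOrganization(states=((1.0, L),), d=d, eta=eta)
        s = np.linspace(0.5, 1.5, 20001)
        S = forward.mct_structure_factor(s, lam, L)
        s_peak = s[np.argmax(S)]
        assert abs(s_peak - 2 * np.pi / d) / (2 * np.pi / d) < 0.02

    def test_domain_error(self):
        with pytest.raises(ParameterDomainError):
            forward.mct_structure_factor(np.array([0.1]), LamellarOrganization.suv(), 0)


class TestPartialIntensity:
    def test_narrow_distribution_limit(self, symmetric_bilayer):
        # sigma -> 0.01 R approaches the monodisperse product below the first shell zero
        s = np.linspace(0.005, np.pi / 50.0 * 0.9, 50)
        comp = MixtureComponent(
            nu=1.0,
            size=SchulzSizeDistribution(R=50.0, sigma=0.5),
            bilayer=symmetric_bilayer,
        )
        I = forward.partial_intensity(s, comp)
        mono = (
            forward.thin_shell_form_factor(s, 50.0) ** 2
            * forward.bilayer_form_factor(s, symmetric_bilayer) ** 2
        )
        assert np.all(np.abs(I / mono - 1) < 0.01)

    def test_monte_carlo_oracle(self, mlv_component):
        rng = np.random.default_rng(11)
        dist = mlv_component.size
        radii = rng.gamma(shape=dist.shape, scale=dist.scale, size=100_000)
        s_pts = np.geomspace(0.02, 5.0, 10)
        I = forward.partial_intensity(s_pts, mlv_component)
        fb2 = forward.bilayer_form_factor(s_pts, mlv_component.bilayer) ** 2
        lam = mlv_component.lamellar
        sf = sum(
            w * forward.mct_structure_factor(s_pts, lam, L)
            for w, (_, L) in zip(lam.normalized_weights(), lam.states)
        )
        for j, s in enumerate(s_pts):
            samples = forward.thin_shell_form_factor(s, radii) ** 2
            mc_mean = samples.mean() * fb2[j] * sf[j]
            mc_se = samples.std(ddof=1) / np.sqrt(radii.size) * fb2[j] * abs(sf[j])
            assert abs(I[j] - mc_mean) < 3 * mc_se + 1e-12 * mc_mean

    def test_suv_has_no_bragg_peak(self, suv_component, mlv_component):
        d = mlv_component.lamellar.d
        s = np.linspace(0.7, 1.3, 2001)  # window around 2 pi / d ~ 0.97
        I_suv = forward.partial_intensity(s, suv_component)
        I_mlv = forward.partial_intensity(s, mlv_component)

        def interior_peaks(I):
            i = np.arange(1, len(I) - 1)
            mask = (I[i] > I[i - 1]) & (I[i] > I[i + 1])
            # count only prominent maxima (> 2% above values ~0.06 nm^-1 away)
            return [
                k for k in i[mask]
                if I[k] > 1.02 * min(I[max(k - 200, 0)], I[min(k + 200, len(I) - 1)])
            ]

        assert not interior_peaks(I_suv)
        peaks = interior_peaks(I_mlv)
        assert peaks
        s_peak = s[peaks[int(np.argmax(I_mlv[peaks]))]]
        assert abs(s_peak - 2 * np.pi / d) / (2 * np.pi / d) < 0.02

    def test_sff_validity_warning(self, symmetric_bilayer):
        comp = MixtureComponent(
            nu=1.0,
            size=SchulzSizeDistribution(R=2.5, sigma=0.2),
            bilayer=symmetric_bilayer,  # thickness 5.6 nm vs diameter 5 nm
        )
        with pytest.warns(UserWarning, match="separated form factor"):
            forward.partial_intensity(np.array([0.1]), comp)


class TestMixtureIntensity:
    def test_single_component_equals_partial(self, suv_model, s_grid):
        I_mix = forward.mixture_intensity(s_grid, suv_model).I
        I_par = forward.partial_intensity(s_grid, suv_model.components[0])
        assert I_mix == pytest.approx(I_par, rel=1e-12)

    def test_duplicate_components_collapse(self, suv_component, s_grid):
        import dataclasses
        m1 = MixtureModel(components=(suv_component,))
        m2 = MixtureModel(components=(
            dataclasses.replace(suv_component, nu=0.3),
            dataclasses.replace(suv_component, nu=0.7),
        ))
        assert forward.mixture_intensity(s_grid, m2).I == pytest.approx(
            forward.mixture_intensity(s_grid, m1).I, rel=1e-12
        )

    def test_scale_homogeneity(self, suv_model, s_grid):
        import dataclasses
        doubled = dataclasses.replace(suv_model, scale=2.0)
        assert forward.mixture_intensity(s_grid, doubled).I == pytest.approx(
            2 * forward.mixture_intensity(s_grid, suv_model).I, rel=1e-12
        )

    def test_positivity(self, mlv_model, s_grid):
        assert np.all(forward.mixture_intensity(s_grid, mlv_model).I > 0)


class TestHeadToHeadDistance:
    def test_single_pair(self):
        # isolated Gaussian pair: maxima exactly at +-z_H1
        p = BilayerParams(z_H1=2.0, sigma_H1=0.2, A2_over_A1=1e-9,
                          z_H2=2.0, sigma_H2=0.2, rho_r=1e-9, sigma_C=0.4)
        assert forward.head_to_head_distance(p) == pytest.approx(4.0, abs=1e-3)

    def test_coincident_pairs(self, symmetric_bilayer):
        assert forward.head_to_head_distance(symmetric_bilayer) == pytest.approx(4.0, abs=1e-3)

    def test_dmpc30_frozen_value(self, dmpc30_bilayer):
        # frozen grid-search oracle value; guards refactors to 0.01 nm
        assert forward.head_to_head_distance(dmpc30_bilayer) == pytest.approx(3.451, abs=0.01)
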