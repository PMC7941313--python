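import dataclasses

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from vesifit import fitting, forward, simulate
from vesifit.errors import InitializationError, ParameterDomainError
from vesifit.fitting import ModelTemplate
from vesifit.models import LamellarOrganization, ScatteringCurve


@pytest.fixture(scope="module")
def suv_fit_setup(suv_model):
    """Small noisy SUV curve + matching template (cheap fits)."""
    spec = simulate.SimulationSpec(
        suv_model, s_min=0.01, s_max=5.0, n_points=150,
        grid="logarithmic", rel_error=0.05, seed=21,
    )
    curve = simulate.simulate_curve(spec)
    template = ModelTemplate(suv_model, symmetric_bilayer=True)
    return curve, template


class TestGuinier:
    def test_exact_guinier_curve(self):
        s = np.linspace(0.001, 0.05, 200)
        I = 7.0 * np.exp(-(50.0**2) * s**2 / 3.0)
        rg, i0 = fitting.guinier_rg(ScatteringCurve(s=s, I=I))
        assert rg == pytest.approx(50.0, rel=1e-6)
        assert i0 == pytest.approx(7.0, rel=1e-6)

    def test_thin_shell_rg(self):
        # a thin spherical shell of radius r has Rg ~ r
        s = np.geomspace(0.002, 0.1, 400)
        I = forward.thin_shell_form_factor(s, 50.0) ** 2
        rg, _ = fitting.guinier_rg(ScatteringCurve(s=s, I=I))
        assert rg == pytest.approx(50.0, rel=0.03)

    def test_increasing_curve_rejected(self):
        s = np.linspace(0.01, 1.0, 50)
        I = np.exp(s**2)
        with pytest.raises(InitializationError):
            fitting.guinier_rg(ScatteringCurve(s=s, I=I))


class TestObjective:
    def test_perfect_model_gives_zero(self, suv_model):
        spec = simulate.SimulationSpec(suv_model, 0.02, 3.0, 80, rel_error=0.0)
        exact = simulate.simulate_curve(spec)
        curve = ScatteringCurve(s=exact.s, I=exact.I, err=0.05 * exact.I)
        template = ModelTemplate(suv_model, symmetric_bilayer=True)
        chi2 = fitting.objective(template.initial_parameters(), curve, template)
        assert chi2 == pytest.approx(0.0, abs=1e-16)

    def test_error_scaling(self, suv_fit_setup):
        curve, template = suv_fit_setup
        pv = template.initial_parameters()
        chi2_1 = fitting.objective(pv, curve, template)
        doubled = ScatteringCurve(s=curve.s, I=curve.I, err=2 * curve.err)
        chi2_2 = fitting.objective(pv, doubled, template)
        assert chi2_2 == pytest.approx(chi2_1 / 4.0, rel=1e-12)

    def test_direct_summation_oracle(self, suv_fit_setup):
        curve, template = suv_fit_setup
        pv = template.initial_parameters()
        chi2 = fitting.objective(pv, curve, template)
        # independent recomputation: profiled scale + explicit sum
        A = forward.mixture_intensity(curve.s, template.build(pv)).I
        w = 1.0 / curve.err**2
        c = (w * curve.I * A).sum() / (w * A * A).sum()
        expected = ((curve.I - c * A) ** 2 * w).sum() / (len(curve) - template.n_free)
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_analytic_gradient_matches_fd(self, benchmark_mlv7):
        curve, truth = benchmark_mlv7
        template = ModelTemplate(truth, symmetric_bilayer=True,
                                 bounds={"c0.z_H1": (1.5, 3.0)})
        pv0 = template.initial_parameters()
        rng = np.random.default_rng(5)
        interior = {
            p.name: p.lower + (0.2 + 0.6 * rng.random()) * (p.upper - p.lower)
            for p in pv0 if p.free
        }
        pv = pv0.with_values(interior)
        _, _, _, _, grad = fitting._objective_parts(pv, curve, template, with_grad=True)
        x = pv.free_values()
        fd = approx_fprime(
            x,
            lambda xx: fitting.objective(pv.with_free_values(xx), curve, template),
            1e-7 * np.maximum(np.abs(x), 1e-3),
        )
        assert grad == pytest.approx(fd, rel=5e-3, abs=1e-6 * np.abs(fd).max())


class TestModelTemplate:
    def test_symmetric_ties(self, mlv_model):
        template = ModelTemplate(mlv_model, symmetric_bilayer=True)
        pv = template.initial_parameters()
        assert "c0.z_H2" not in pv
        model = template.build(pv.with_values({"c0.z_H1": 2.1}))
        assert model.components[0].bilayer.z_H2 == 2.1

    def test_weights_free_and_renormalized(self, mlv_model):
        template = ModelTemplate(mlv_model, symmetric_bilayer=True)
        pv = template.initial_parameters()
        assert pv["c0.w1"].free and pv["c0.w7"].free
        # raw weights are renormalized when the model is built
        model = template.build(pv.with_values({"c0.w1": 2.0, "c0.w7": 2.0}))
        w = model.components[0].lamellar.normalized_weights()
        assert w.sum() == pytest.approx(1.0)

    def test_fit_weights_off(self, mlv_model):
        template = ModelTemplate(mlv_model, symmetric_bilayer=True, fit_weights=False)
        pv = template.initial_parameters()
        assert not pv["c0.w1"].free and not pv["c0.w7"].free

    def test_bounds_respected_by_build(self, mlv_model):
        template = ModelTemplate(mlv_model, symmetric_bilayer=True)
        pv = template.initial_parameters()
        # sigma is kept below half the mean radius even if pushed there
        model = template.build(pv.with_values({"c0.R": 20.0, "c0.sigma": 15.0}, clip=True))
        comp = model.components[0]
        assert comp.size.sigma <= 0.5 * comp.size.R

    def test_single_component_nu_fixed(self, mlv_model):
        template = ModelTemplate(mlv_model)
        assert not template.initial_parameters()["c0.nu"].free

    def test_default_bounds(self, mlv_model):
        pv = ModelTemplate(mlv_model).initial_parameters()
        assert (pv["c0.z_H1"].lower, pv["c0.z_H1"].upper) == (1.5, 2.5)
        assert (pv["c0.sigma_H1"].lower, pv["c0.sigma_H1"].upper) == (0.1, 0.3)
        assert pv["c0.sigma"].lower == pytest.approx(0.02 * 50.0)
        assert pv["c0.sigma"].upper == pytest.approx(0.5 * 50.0)


class TestFit:
    def test_fixed_point_from_truth(self, suv_model):
        # noiseless self-generated curve, start at truth -> chi2 ~ 0
        spec = simulate.SimulationSpec(suv_model, 0.02, 3.0, 100, rel_error=0.0)
        exact = simulate.simulate_curve(spec)
        curve = ScatteringCurve(s=exact.s, I=exact.I, err=0.05 * exact.I)
        template = ModelTemplate(suv_model, symmetric_bilayer=True)
        result = fitting.fit(curve, template, max_iter=50)
        assert result.chi2_reduced < 1e-8
        truth = suv_model.components[0]
        assert result.value("c0.R") == pytest.approx(truth.size.R, rel=1e-3)
        assert result.value("c0.z_H1") == pytest.approx(truth.bilayer.z_H1, rel=1e-3)

    def test_monotonicity_and_bounds(self, suv_fit_setup):
        curve, template = suv_fit_setup
        start = {"c0.R": 60.0, "c0.sigma": 7.0, "c0.rho_r": 1.2}
        pv_start = template.initial_parameters().with_values(start, clip=True)
        chi2_start = fitting.objective(pv_start, curve, template)
        result = fitting.fit(curve, template, x0=start)
        assert result.chi2_reduced <= chi2_start
        for p in result.parameters:
            assert p.lower <= p.value <= p.upper

    def test_determinism(self, suv_fit_setup):
        curve, template = suv_fit_setup
        r1 = fitting.fit(curve, template, seed=3)
        r2 = fitting.fit(curve, template, seed=3)
        assert r1.parameters.values() == r2.parameters.values()
        assert r1.chi2_reduced == r2.chi2_reduced

    def test_requires_errors(self, suv_fit_setup, suv_model):
        _, template = suv_fit_setup
        s = np.linspace(0.02, 1.0, 30)
        bare = ScatteringCurve(s=s, I=np.exp(-s))
        with pytest.raises(ParameterDomainError):
            fitting.fit(bare, template)

    def test_recovers_suv_parameters(self, suv_fit_setup, suv_model):
        curve, template = suv_fit_setup
        start = {"c0.R": 58.0, "c0.sigma": 6.0, "c0.z_H1": 2.2,
                 "c0.sigma_H1": 0.24, "c0.rho_r": 1.2, "c0.sigma_C": 0.5}
        result = fitting.fit(curve, template, x0=start)
        truth = suv_model.components[0]
        assert result.value("c0.R") == pytest.approx(truth.size.R, rel=0.05)
        assert result.value("c0.sigma") / result.value("c0.R") == pytest.approx(
            truth.size.polydispersity, abs=0.03
        )


class TestEstimateErrors:
    def test_noiseless_restarts_agree(self, suv_model):
        spec = simulate.SimulationSpec(suv_model, 0.02, 3.0, 100, rel_error=0.0)
        exact = simulate.simulate_curve(spec)
        curve = ScatteringCurve(s=exact.s, I=exact.I, err=0.01 * exact.I)
        template = ModelTemplate(
            suv_model, symmetric_bilayer=True,
            fixed=["c0.sigma_H1", "c0.rho_r", "c0.sigma_C"],
        )
        result = fitting.estimate_errors(curve, template, n_restarts=4, seed=2,
                                         perturbation=0.15)
        assert result.param_errors is not None
        for name, err in result.param_errors.items():
            scale = max(abs(result.value(name)), 1.0)
            assert err < 1e-3 * scale, name

    def test_fixed_parameters_have_no_error(self, suv_model):
        spec = simulate.SimulationSpec(suv_model, 0.02, 3.0, 100, rel_error=0.0)
        exact = simulate.simulate_curve(spec)
        curve = ScatteringCurve(s=exact.s, I=exact.I, err=0.01 * exact.I)
        template = ModelTemplate(
            suv_model, symmetric_bilayer=True,
            fixed=["c0.sigma_H1", "c0.rho_r", "c0.sigma_C"],
        )
        result = fitting.estimate_errors(curve, template, n_restarts=3, seed=2,
                                         perturbation=0.15)
        assert result.param_errors is not None
        assert "c0.rho_r" not in result.param_errors
        assert "c0.nu" not in result.param_errors


class TestScreening:
    def test_empty_candidates(self, suv_fit_setup):
        curve, template = suv_fit_setup
        with pytest.raises(ParameterDomainError):
            fitting.screen_models(curve, template.model, [])

    def test_lamellarity_ladder(self):
        assert fitting.lamellarity_ladder(1).states == ((1.0, 1),)
        lad = fitting.lamellarity_ladder(4, d=6.0, eta=0.05)
        assert [L for _, L in lad.states] == [1, 2, 3, 4]
        assert lad.normalized_weights() == pytest.approx(np.full(4, 0.25))
        with pytest.raises(ParameterDomainError):
            fitting.lamellarity_ladder(0)
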