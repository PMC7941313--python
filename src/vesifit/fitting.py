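"""Parameter estimation from measured curves.

Bounded quasi-Newton (L-BFGS-B) minimization of the reduced chi-square,
with the global intensity scale (and optionally a flat background)
profiled out analytically at every evaluation.  Gradients are analytic
for all parameters except the size-distribution pair (R, sigma), which
use central differences of the size-averaged shell factor only.

The public :func:`fit` is staged for robustness from poor starts:
an optional size-only prefit, a 1-D scan over the lamellar repeat
distance, then quasi-Newton rounds restarted until the chi-square
stops improving.  Also provides Guinier-based radius initialization,
restart-ensemble error estimation and screening over lamellar
organization hypotheses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from . import forward
from .errors import InitializationError, ParameterDomainError
from .models import (
    BilayerParams,
    LamellarOrganization,
    MixtureComponent,
    MixtureModel,
    ScatteringCurve,
    SchulzSizeDistribution,
)
from .parameters import Parameter, ParameterVector

__all__ = [
    "ModelTemplate",
    "FitResult",
    "guinier_rg",
    "objective",
    "fit",
    "fit_with_initialization",
    "estimate_errors",
    "screen_models",
    "lamellarity_ladder",
]

# Physically motivated default bounds (nm where dimensional).
DEFAULT_BOUNDS = {
    "z_H": (1.5, 2.5),
    "sigma_H": (0.1, 0.3),
    "A2_over_A1": (0.1, 5.0),
    "rho_r": (0.5, 3.0),
    "sigma_C": (0.15, 1.0),
    "eta": (0.0, 0.5),
    "nu": (0.0, 1.0),
    "w": (0.0, 5.0),
}

_SQRT2PI = np.sqrt(2.0 * np.pi)


class ModelTemplate:
    """Binds a :class:`MixtureModel` to a flat :class:`ParameterVector`.

    The template model supplies structure (number of components,
    lamellarity states) and starting values; the parameter vector holds
    the free/fixed flags and bounds the optimizer works with.

    Parameters
    ----------
    model : MixtureModel
        Starting model.  Its ``scale``/``background`` are not part of
        the vector: the scale is profiled analytically during fitting.
    symmetric_bilayer : bool
        Tie the second headgroup pair to the first (z_H2 = z_H1,
        sigma_H2 = sigma_H1, A2/A1 = 1 fixed), halving the density
        parameters for symmetric profiles.
    fit_weights : bool
        Free the lamellarity occupancy weights.  The first state's raw
        weight stays fixed as a normalization gauge; weights are
        renormalized to sum to 1 when the model is built.
    fit_background : bool
        Profile an additive flat background along with the scale.
    bounds : mapping, optional
        Per-parameter ``name -> (lower, upper)`` overrides.
    fixed : sequence of str, optional
        Parameter names to hold fixed at their template value.
    n_nodes : int
        Size-integral quadrature nodes passed to the forward model.

    Parameter names are ``c<k>.<field>``, e.g. ``c0.R``, ``c0.sigma``,
    ``c0.z_H1``, ``c0.eta``, ``c0.w2`` (raw occupancy weight of the
    L = 2 state).
    """

    def __init__(
        self,
        model: MixtureModel,
        *,
        symmetric_bilayer: bool = False,
        fit_weights: bool = True,
        fit_background: bool = False,
        bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
        fixed: Sequence[str] = (),
        n_nodes: int = forward.DEFAULT_SIZE_NODES,
    ):
        self.model = model
        self.symmetric_bilayer = symmetric_bilayer
        self.fit_weights = fit_weights
        self.fit_background = fit_background
        self.n_nodes = n_nodes
        self._bounds = dict(bounds or {})
        self._fixed = set(fixed)
        self._pv = self._build_vector()

    def replace(self, **overrides) -> "ModelTemplate":
        """Copy with some construction arguments replaced."""
        kwargs = dict(
            model=self.model,
            symmetric_bilayer=self.symmetric_bilayer,
            fit_weights=self.fit_weights,
            fit_background=self.fit_background,
            bounds=self._bounds,
            fixed=tuple(self._fixed),
            n_nodes=self.n_nodes,
        )
        kwargs.update(overrides)
        return ModelTemplate(kwargs.pop("model"), **kwargs)

    def with_only_free(self, names: Sequence[str]) -> "ModelTemplate":
        """Copy in which only ``names`` remain free."""
        fixed = set(self._fixed)
        fixed.update(n for n in self._pv.names if n not in names)
        return self.replace(fixed=tuple(fixed))

    # -- vector construction -------------------------------------------------

    def _bound(self, name: str, default: Tuple[float, float]) -> Tuple[float, float]:
        return self._bounds.get(name, default)

    def _param(self, name: str, value: float, default_bounds: Tuple[float, float],
               free: bool = True) -> Parameter:
        lo, hi = self._bound(name, default_bounds)
        if name in self._fixed:
            free = False
        value = float(np.clip(value, lo, hi))
        return Parameter(name, value, lo, hi, free=free)

    def _build_vector(self) -> ParameterVector:
        params: List[Parameter] = []
        n_comp = len(self.model.components)
        nu0 = self.model.normalized_fractions()
        for k, comp in enumerate(self.model.components):
            pre = f"c{k}."
            params.append(
                self._param(pre + "nu", nu0[k], DEFAULT_BOUNDS["nu"], free=n_comp > 1)
            )
            R0 = comp.size.R
            params.append(self._param(pre + "R", R0, (0.3 * R0, 3.0 * R0)))
            params.append(
                self._param(pre + "sigma", comp.size.sigma, (0.02 * R0, 0.5 * R0))
            )
            b = comp.bilayer
            params.append(self._param(pre + "z_H1", b.z_H1, DEFAULT_BOUNDS["z_H"]))
            params.append(
                self._param(pre + "sigma_H1", b.sigma_H1, DEFAULT_BOUNDS["sigma_H"])
            )
            if not self.symmetric_bilayer:
                params.append(
                    self._param(pre + "A2_over_A1", b.A2_over_A1, DEFAULT_BOUNDS["A2_over_A1"])
                )
                params.append(self._param(pre + "z_H2", b.z_H2, DEFAULT_BOUNDS["z_H"]))
                params.append(
                    self._param(pre + "sigma_H2", b.sigma_H2, DEFAULT_BOUNDS["sigma_H"])
                )
            params.append(self._param(pre + "rho_r", b.rho_r, DEFAULT_BOUNDS["rho_r"]))
            params.append(self._param(pre + "sigma_C", b.sigma_C, DEFAULT_BOUNDS["sigma_C"]))
            lam = comp.lamellar
            if not lam.is_unilamellar:
                d0 = lam.d
                params.append(self._param(pre + "d", d0, (0.7 * d0, 1.3 * d0)))
                params.append(self._param(pre + "eta", lam.eta, DEFAULT_BOUNDS["eta"]))
                w0 = lam.normalized_weights()
                # raw weights are renormalized at build time, so the
                # scaling direction is flat and needs no explicit gauge
                for i, (_, L) in enumerate(lam.states):
                    params.append(
                        self._param(pre + f"w{L}", w0[i], DEFAULT_BOUNDS["w"],
                                    free=self.fit_weights)
                    )
        return ParameterVector(params)

    # -- public API ----------------------------------------------------------

    def initial_parameters(self) -> ParameterVector:
        return self._pv

    @property
    def n_free(self) -> int:
        """Free parameters seen by the optimizer, plus the profiled
        scale (and background if enabled)."""
        return self._pv.n_free + 1 + int(self.fit_background)

    def build(self, pv: ParameterVector) -> MixtureModel:
        """Realize a MixtureModel (unit scale, zero background) from a
        parameter vector."""
        comps = []
        for k, comp in enumerate(self.model.components):
            pre = f"c{k}."
            R = pv.value(pre + "R")
            sigma = min(pv.value(pre + "sigma"), 0.499 * R)  # keep sigma/R <= 0.5
            size = SchulzSizeDistribution(R=R, sigma=sigma)
            if self.symmetric_bilayer:
                bil = BilayerParams(
                    z_H1=pv.value(pre + "z_H1"),
                    sigma_H1=pv.value(pre + "sigma_H1"),
                    A2_over_A1=1.0,
                    z_H2=pv.value(pre + "z_H1"),
                    sigma_H2=pv.value(pre + "sigma_H1"),
                    rho_r=pv.value(pre + "rho_r"),
                    sigma_C=pv.value(pre + "sigma_C"),
                )
            else:
                bil = BilayerParams(
                    z_H1=pv.value(pre + "z_H1"),
                    sigma_H1=pv.value(pre + "sigma_H1"),
                    A2_over_A1=pv.value(pre + "A2_over_A1"),
                    z_H2=pv.value(pre + "z_H2"),
                    sigma_H2=pv.value(pre + "sigma_H2"),
                    rho_r=pv.value(pre + "rho_r"),
                    sigma_C=pv.value(pre + "sigma_C"),
                )
            lam0 = comp.lamellar
            if lam0.is_unilamellar:
                lam = lam0
            else:
                states = tuple(
                    (max(pv.value(pre + f"w{L}"), 0.0), L) for _, L in lam0.states
                )
                if sum(w for w, _ in states) <= 0:
                    states = ((1.0, lam0.states[0][1]),) + states[1:]
                lam = LamellarOrganization(
                    states=states, d=pv.value(pre + "d"), eta=pv.value(pre + "eta")
                )
            comps.append(
                MixtureComponent(
                    nu=max(pv.value(pre + "nu"), 0.0), size=size, bilayer=bil, lamellar=lam
                )
            )
        if all(c.nu == 0 for c in comps):
            comps[0] = dataclasses.replace(comps[0], nu=1.0)
        return MixtureModel(components=tuple(comps), scale=1.0, background=0.0)


@dataclass
class FitResult:
    """Outcome of one bounded quasi-Newton fit."""

    parameters: ParameterVector
    chi2_reduced: float
    model: MixtureModel
    model_curve: ScatteringCurve
    converged: bool
    n_free: int
    n_iterations: int
    termination: str
    seed: Optional[int] = None
    param_errors: Optional[Dict[str, float]] = None
    n_restarts_converged: int = 0
    hypothesis: Optional[LamellarOrganization] = None

    def value(self, name: str) -> float:
        return self.parameters.value(name)


# -- Guinier initialization --------------------------------------------------

def guinier_rg(
    curve: ScatteringCurve,
    s_rg_max: float = 1.3,
    min_points: int = 10,
    max_iter: int = 50,
) -> Tuple[float, float]:
    """Radius of gyration and I(0) from the Guinier approximation
    ``ln I = ln I0 - Rg^2 s^2 / 3``.

    Weighted linear regression of ln I vs s^2 with iterative range
    selection: starting from the low-angle quarter of the curve, the
    range is re-restricted to ``s * Rg < s_rg_max`` until stable.

    Raises
    ------
    InitializationError
        If no valid Guinier range exists (non-negative slope, too few
        points, or non-positive intensities at low angles).
    """
    s, I = curve.s, curve.I
    if curve.err is not None:
        w_ln = (I / curve.err) ** 2  # var(ln I) = (err / I)^2
    else:
        w_ln = np.ones_like(I)
    mask = np.zeros_like(s, dtype=bool)
    mask[: max(min_points, s.size // 4)] = True
    rg = None
    intercept = 0.0
    for _ in range(max_iter):
        sel = mask & (I > 0)
        if sel.sum() < min_points:
            raise InitializationError(f"fewer than {min_points} points in Guinier range")
        x = s[sel] ** 2
        y = np.log(I[sel])
        w = w_ln[sel]
        W = w.sum()
        xbar = (w * x).sum() / W
        ybar = (w * y).sum() / W
        sxx = (w * (x - xbar) ** 2).sum()
        slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
        if slope >= 0:
            raise InitializationError("no valid Guinier range: non-negative slope")
        intercept = ybar - slope * xbar
        rg = float(np.sqrt(-3.0 * slope))
        new_mask = s * rg < s_rg_max
        if new_mask.sum() < min_points:
            new_mask = np.zeros_like(mask)
            new_mask[:min_points] = True
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return rg, float(np.exp(intercept))


# -- objective and analytic gradient -----------------------------------------

def _profiled_scale(
    A: np.ndarray, curve: ScatteringCurve, fit_background: bool
) -> Tuple[float, float]:
    """Weighted-least-squares optimum of I_obs ~ c * A (+ b)."""
    w = 1.0 / curve.err**2
    I = curve.I
    if fit_background:
        saa = (w * A * A).sum()
        sa = (w * A).sum()
        s1 = w.sum()
        sia = (w * I * A).sum()
        si = (w * I).sum()
        det = saa * s1 - sa * sa
        if det > 0:
            c = (sia * s1 - si * sa) / det
            b = (si * saa - sia * sa) / det
            if c > 0 and b >= 0:
                return float(c), float(b)
        # fall back to scale-only if the joint solution is unphysical
    c = (w * I * A).sum() / (w * A * A).sum()
    return float(max(c, 1e-30)), 0.0


def _ffb_derivs(s: np.ndarray, b: BilayerParams, symmetric: bool) -> Dict[str, np.ndarray]:
    """Analytic partials of the flat-bilayer form factor."""
    A1, A2 = b.A1, b.A2_over_A1 * b.A1
    e1 = np.exp(-(s**2) * b.sigma_H1**2 / 2)
    e2 = np.exp(-(s**2) * b.sigma_H2**2 / 2)
    eC = np.exp(-(s**2) * b.sigma_C**2 / 2)
    c1, s1 = np.cos(s * b.z_H1), np.sin(s * b.z_H1)
    c2, s2 = np.cos(s * b.z_H2), np.sin(s * b.z_H2)
    d: Dict[str, np.ndarray] = {}
    dz1 = -2.0 * A1 * b.sigma_H1 * s * s1 * e1
    dsig1 = 2.0 * A1 * c1 * e1 * (1.0 - s**2 * b.sigma_H1**2)
    if symmetric:
        # second pair tied to the first (z_H2 = z_H1, sigma_H2 = sigma_H1)
        dz1 = dz1 + (-2.0 * A2 * b.sigma_H2 * s * s2 * e2)
        dsig1 = dsig1 + 2.0 * A2 * c2 * e2 * (1.0 - s**2 * b.sigma_H2**2)
    else:
        d["A2_over_A1"] = _SQRT2PI * 2.0 * A1 * b.sigma_H2 * c2 * e2
        d["z_H2"] = _SQRT2PI * (-2.0 * A2 * b.sigma_H2 * s * s2 * e2)
        d["sigma_H2"] = _SQRT2PI * 2.0 * A2 * c2 * e2 * (1.0 - s**2 * b.sigma_H2**2)
    d["z_H1"] = _SQRT2PI * dz1
    d["sigma_H1"] = _SQRT2PI * dsig1
    d["rho_r"] = -_SQRT2PI * A1 * b.sigma_C * eC
    d["sigma_C"] = -_SQRT2PI * b.rho_r * A1 * eC * (1.0 - s**2 * b.sigma_C**2)
    return d


def _mct_derivs(
    s: np.ndarray, lam: LamellarOrganization, L: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Partials of the modified Caille structure factor wrt (d, eta)."""
    d, eta = lam.d, lam.eta
    dS_dd = np.zeros_like(s)
    dS_deta = np.zeros_like(s)
    if L < 2:
        return dS_dd, dS_deta
    pref = (d / (2.0 * np.pi)) ** 2 * s**2  # a = pref * eta
    a = pref * eta
    da_dd = 2.0 * a / d
    da_deta = pref
    for m in range(1, L):
        k = forward.EULER_GAMMA + np.log(np.pi * m)
        damp = np.exp(-a * k)
        cosm, sinm = np.cos(m * s * d), np.sin(m * s * d)
        coeff = 2.0 * (L - m)
        dS_dd += coeff * damp * (-m * s * sinm - cosm * k * da_dd)
        dS_deta += coeff * cosm * damp * (-k) * da_deta
    return dS_dd, dS_deta


def _shell_derivs(
    s: np.ndarray, size: SchulzSizeDistribution, n_nodes: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Central-difference partials of the size-averaged shell factor
    wrt (R, sigma); only this factor depends on the size parameters."""
    hR = 1e-5 * size.R
    hs = 1e-5 * size.sigma
    f = forward._size_averaged_shell
    gR = (
        f(s, SchulzSizeDistribution(size.R + hR, size.sigma), n_nodes)
        - f(s, SchulzSizeDistribution(size.R - hR, size.sigma), n_nodes)
    ) / (2.0 * hR)
    gs = (
        f(s, SchulzSizeDistribution(size.R, size.sigma + hs), n_nodes)
        - f(s, SchulzSizeDistribution(size.R, size.sigma - hs), n_nodes)
    ) / (2.0 * hs)
    return gR, gs


def _objective_parts(pv, curve, template, with_grad: bool):
    """Reduced chi-square, profiled (scale, background), model shape and
    (optionally) the gradient over free parameters.

    The gradient of the profiled objective needs only the partial
    derivative at the optimal scale (envelope theorem).
    """
    model = template.build(pv)
    s = curve.s
    nu_t = model.normalized_fractions()
    terms = []
    A = np.zeros_like(s)
    for k, comp in enumerate(model.components):
        G = forward._size_averaged_shell(s, comp.size, template.n_nodes)
        F = forward.bilayer_form_factor(s, comp.bilayer)
        lam = comp.lamellar
        wt = lam.normalized_weights()
        S_list = [forward.mct_structure_factor(s, lam, L) for _, L in lam.states]
        Sbar = np.zeros_like(s)
        for w_i, S_i in zip(wt, S_list):
            Sbar += w_i * S_i
        A_k = G * F**2 * Sbar
        A += nu_t[k] * A_k
        terms.append((comp, G, F, Sbar, S_list, A_k))
    c, b = _profiled_scale(A, curve, template.fit_background)
    w = 1.0 / curve.err**2
    resid = curve.I - c * A - b
    dof = max(len(curve) - template.n_free, 1)
    chi2 = float((w * resid**2).sum() / dof)
    if not with_grad:
        return chi2, c, b, A, None
    # dchi2/dp = -(2 c / dof) * sum w resid dA/dp
    wres = w * resid
    grad = np.zeros(pv.n_free)
    free_index = {n: i for i, n in enumerate(pv.free_names)}
    nu_raw = np.array(
        [max(pv.value(f"c{k}.nu"), 0.0) for k in range(len(model.components))]
    )
    nu_sum = nu_raw.sum()

    def put(name: str, dA: np.ndarray) -> None:
        i = free_index.get(name)
        if i is not None:
            grad[i] = -(2.0 * c / dof) * float((wres * dA).sum())

    for k, (comp, G, F, Sbar, S_list, A_k) in enumerate(terms):
        pre = f"c{k}."
        if nu_sum > 0:
            put(pre + "nu", (A_k - A) / nu_sum)
        base = nu_t[k]
        if pre + "R" in free_index or pre + "sigma" in free_index:
            gR, gs = _shell_derivs(s, comp.size, template.n_nodes)
            fs2 = F**2 * Sbar
            clipped = pv.value(pre + "sigma") > 0.499 * pv.value(pre + "R")
            if clipped:
                # sigma_eff = 0.499 R rides along with R
                put(pre + "R", base * (gR + 0.499 * gs) * fs2)
            else:
                put(pre + "R", base * gR * fs2)
                put(pre + "sigma", base * gs * fs2)
        gfs = base * G * Sbar * 2.0 * F
        for name, dF in _ffb_derivs(s, comp.bilayer, template.symmetric_bilayer).items():
            put(pre + name, gfs * dF)
        lam = comp.lamellar
        if not lam.is_unilamellar:
            gf2 = base * G * F**2
            wt = lam.normalized_weights()
            dS_dd = np.zeros_like(s)
            dS_de = np.zeros_like(s)
            for w_i, (_, L_i) in zip(wt, lam.states):
                dd, de = _mct_derivs(s, lam, L_i)
                dS_dd += w_i * dd
                dS_de += w_i * de
            put(pre + "d", gf2 * dS_dd)
            put(pre + "eta", gf2 * dS_de)
            w_sum = sum(wi for wi, _ in lam.states)
            for (w_i_raw, L_i), S_i in zip(lam.states, S_list):
                put(pre + f"w{L_i}", gf2 * (S_i - Sbar) / w_sum)
    return chi2, c, b, A, grad


def objective(
    pv: ParameterVector,
    curve: ScatteringCurve,
    template: ModelTemplate,
) -> float:
    """Reduced chi-square of the model against the curve, with the
    scale (and background, if enabled) set to their analytic optima."""
    chi2, _, _, _, _ = _objective_parts(pv, curve, template, with_grad=False)
    return chi2


# -- fitting -----------------------------------------------------------------

def _minimize_once(curve, template, pv0, max_iter, ftol, gtol, use_grad=True):
    """One L-BFGS-B run in box-normalized coordinates."""
    bounds = pv0.free_bounds()
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo

    def from_unit(u):
        return lo + np.clip(u, 0.0, 1.0) * span

    if use_grad:
        def fun(u):
            pv = pv0.with_free_values(from_unit(u))
            chi2, _, _, _, g = _objective_parts(pv, curve, template, with_grad=True)
            return chi2, g * span
    else:
        def fun(u):
            pv = pv0.with_free_values(from_unit(u))
            return objective(pv, curve, template)

    u0 = (pv0.free_values() - lo) / span
    res = optimize.minimize(
        fun,
        u0,
        jac=use_grad if use_grad else None,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * len(u0),
        options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol,
                 "maxcor": 20, "maxfun": 10**6},
    )
    chi2_start = objective(pv0, curve, template)
    if res.fun > chi2_start:  # guard monotonicity
        return pv0, chi2_start, False, 0, "no improvement over start"
    pv_best = pv0.with_free_values(from_unit(res.x))
    msg = res.message if isinstance(res.message, str) else str(res.message)
    success = bool(res.success)
    if not success and use_grad:
        # the line search can give up ("ABNORMAL") at a solution whose
        # projected gradient is already negligible; certify it directly
        _, g = fun(res.x)
        u = np.clip(res.x, 0.0, 1.0)
        pg = np.where(u <= 0.0, np.minimum(g, 0.0),
                      np.where(u >= 1.0, np.maximum(g, 0.0), g))
        if np.max(np.abs(pg)) <= 1e-4 * max(1.0, abs(float(res.fun))):
            success, msg = True, "projected gradient negligible"
    return pv_best, float(res.fun), success, int(res.nit), msg


def _scan_parameter(curve, template, pv, name, n_scan):
    """1-D preconditioning scan of one free parameter over its bounds;
    keeps the best of (scan grid + current value), so a start already
    at the optimum is never degraded."""
    if name not in pv or not pv[name].free:
        return pv
    p = pv[name]
    candidates = np.append(np.linspace(p.lower, p.upper, n_scan), p.value)
    chi2s = [objective(pv.with_values({name: v}), curve, template) for v in candidates]
    return pv.with_values({name: float(candidates[int(np.argmin(chi2s))])})


_SCAN_POLYDISPERSITIES = (0.02, 0.05, 0.10, 0.15, 0.22, 0.30, 0.40)
_SCAN_ETAS = (0.0, 0.02, 0.05, 0.10, 0.15, 0.22, 0.30, 0.40)


def _component_context(curve, template, pv, k):
    """(model, component k, its normalized fraction, summed intensity of
    the other components) for the linear-subspace scans."""
    model = template.build(pv)
    s = curve.s
    nu_t = model.normalized_fractions()
    rest = np.zeros_like(s)
    for j, comp in enumerate(model.components):
        if j != k and nu_t[j] > 0:
            rest += nu_t[j] * forward.partial_intensity(
                s, comp, n_nodes=template.n_nodes, check_sff=False
            )
    return model, model.components[k], nu_t[k], rest


def _nnls_candidate(A_cols, rest, curve, fit_background):
    """Weighted NNLS solve of I ~ [rest | columns | bg]; returns the
    coefficient vector (aligned with A_cols) and the chi-square."""
    err = curve.err
    cols = []
    has_rest = bool(np.any(rest))
    if has_rest:
        cols.append(rest)
    cols.extend(A_cols)
    if fit_background:
        cols.append(np.ones_like(err))
    A = np.stack(cols, axis=1) / err[:, None]
    b = curve.I / err
    q, rnorm = optimize.nnls(A, b)
    lo = 1 if has_rest else 0
    hi = lo + len(A_cols)
    return q[lo:hi], float(rnorm**2)


def _weights_from_coeffs(pv, k, states, coeffs):
    """Convert NNLS state coefficients back into raw occupancy weights
    (normalized to sum 1; the overall magnitude is a flat direction)."""
    q = np.maximum(np.asarray(coeffs, dtype=float), 0.0)
    if q.sum() <= 0:
        return {}
    q = q / q.sum()
    return {
        f"c{k}.w{L}": float(q[i])
        for i, (_, L) in enumerate(states)
        if pv[f"c{k}.w{L}"].free
    }


def _scan_linear(curve, template, pv, k, shape_updates_list):
    """Generic preconditioning scan for component ``k``: for every
    candidate update of the nonlinear shape parameters, globally solve
    the linear (scale, occupancy weights, background) subspace by NNLS
    and keep the overall best candidate.  The incumbent values are part
    of the candidate list and the result is objective-guarded, so the
    scan never degrades the fit."""
    model, comp, nu_k, rest = _component_context(curve, template, pv, k)
    if nu_k <= 0:
        return pv
    s = curve.s
    lam0 = comp.lamellar
    weight_names = [f"c{k}.w{L}" for _, L in lam0.states]
    weights_free = any(n in pv and pv[n].free for n in weight_names)
    chi2_now = objective(pv, curve, template)
    best = (chi2_now, {}, None)
    for updates in shape_updates_list:
        trial = pv.with_values(updates, clip=True)
        tmodel = template.build(trial)
        tcomp = tmodel.components[k]
        G = forward._size_averaged_shell(s, tcomp.size, template.n_nodes)
        F2 = forward.bilayer_form_factor(s, tcomp.bilayer) ** 2
        base = nu_k * G * F2
        lam = tcomp.lamellar
        if weights_free and not lam.is_unilamellar:
            cols = [
                base * forward.mct_structure_factor(s, lam, L) for _, L in lam.states
            ]
            coeffs, chi2 = _nnls_candidate(cols, rest, curve, template.fit_background)
        else:
            wt = lam.normalized_weights()
            sf = np.zeros_like(s)
            for w_i, (_, L) in zip(wt, lam.states):
                sf += w_i * forward.mct_structure_factor(s, lam, L)
            coeffs, chi2 = _nnls_candidate(
                [base * sf], rest, curve, template.fit_background
            )
            coeffs = None
        dof = max(len(curve) - template.n_free, 1)
        chi2 /= dof
        if chi2 < best[0]:
            best = (chi2, updates, coeffs)
    chi2_b, updates, coeffs = best
    if not updates and coeffs is None:
        return pv
    trial = pv.with_values(updates, clip=True)
    if coeffs is not None:
        tlam = template.build(trial).components[k].lamellar
        trial = trial.with_values(
            _weights_from_coeffs(trial, k, tlam.states, coeffs), clip=True
        )
    if objective(trial, curve, template) <= chi2_now:
        return trial
    return pv


def _scan_size(curve, template, pv, k, n_R=61):
    """Joint (mean radius, polydispersity) preconditioning scan with the
    linear subspace solved per candidate.  The shell oscillation phase
    makes the chi-square heavily multimodal in R with basin widths set
    by sigma, and wrong occupancy weights can mask the true basin, so
    all three must move together."""
    name_R, name_s = f"c{k}.R", f"c{k}.sigma"
    if name_R not in pv or not pv[name_R].free:
        return pv
    p_R = pv[name_R]
    radii = np.linspace(p_R.lower, p_R.upper, n_R)
    if name_s in pv and pv[name_s].free:
        candidates = [
            {name_R: R, name_s: pd * R}
            for R in radii
            for pd in _SCAN_POLYDISPERSITIES
        ]
    else:
        candidates = [{name_R: R} for R in radii]
    candidates.append({})  # incumbent
    return _scan_linear(curve, template, pv, k, candidates)


def _scan_joint(curve, template, pv, k, n_R=41, n_z=21,
                pds=(0.02, 0.05, 0.10, 0.15, 0.22, 0.30)):
    """Joint (R, polydispersity, z_H1) scan with the linear subspace
    solved per candidate.

    Wrong radius and wrong headgroup position compensate each other, so
    neither 1-D scan can escape their joint trap.  The factorization
    I = G(R, sigma) * F^2(bilayer) * S(lamellar) keeps the full grid
    cheap: G is evaluated per size candidate, F^2 per z candidate, and
    only the NNLS solve runs per combination."""
    name_R, name_s, name_z = f"c{k}.R", f"c{k}.sigma", f"c{k}.z_H1"
    if name_R not in pv or not pv[name_R].free:
        return pv
    model, comp, nu_k, rest = _component_context(curve, template, pv, k)
    if nu_k <= 0:
        return pv
    s = curve.s
    chi2_now = objective(pv, curve, template)
    p_R = pv[name_R]
    size_cands = [(R, pd * R) for R in np.linspace(p_R.lower, p_R.upper, n_R)
                  for pd in pds]
    size_cands.append((p_R.value, pv.value(name_s)))
    if name_z in pv and pv[name_z].free:
        p_z = pv[name_z]
        z_cands = list(np.linspace(p_z.lower, p_z.upper, n_z)) + [p_z.value]
    else:
        z_cands = [pv.value(name_z)] if name_z in pv else [comp.bilayer.z_H1]
    lam = comp.lamellar
    weight_names = [f"c{k}.w{L}" for _, L in lam.states]
    weights_free = any(n in pv and pv[n].free for n in weight_names)
    if weights_free and not lam.is_unilamellar:
        S_cols = [forward.mct_structure_factor(s, lam, L) for _, L in lam.states]
    else:
        wt = lam.normalized_weights()
        sf = np.zeros_like(s)
        for w_i, (_, L) in zip(wt, lam.states):
            sf += w_i * forward.mct_structure_factor(s, lam, L)
        S_cols = [sf]
    F2_list = []
    for z in z_cands:
        trial = pv.with_values({name_z: z}, clip=True) if name_z in pv else pv
        bil = template.build(trial).components[k].bilayer
        F2_list.append(forward.bilayer_form_factor(s, bil) ** 2)
    dof = max(len(curve) - template.n_free, 1)
    best = (np.inf, None, None, None)
    for R, sig in size_cands:
        trial = pv.with_values({name_R: R, name_s: sig}, clip=True)
        size = template.build(trial).components[k].size
        G = forward._size_averaged_shell(s, size, template.n_nodes)
        base = nu_k * G
        for z, F2 in zip(z_cands, F2_list):
            cols = [base * F2 * Si for Si in S_cols]
            coeffs, chi2 = _nnls_candidate(cols, rest, curve, template.fit_background)
            chi2 /= dof
            if chi2 < best[0]:
                best = (chi2, (R, sig), z, coeffs if weights_free else None)
    _, (R_b, s_b), z_b, coeffs = best
    updates = {name_R: R_b, name_s: s_b}
    if name_z in pv and pv[name_z].free:
        updates[name_z] = z_b
    trial = pv.with_values(updates, clip=True)
    if coeffs is not None and not lam.is_unilamellar:
        tlam = template.build(trial).components[k].lamellar
        trial = trial.with_values(
            _weights_from_coeffs(trial, k, tlam.states, coeffs), clip=True
        )
    if objective(trial, curve, template) <= chi2_now:
        return trial
    return pv


def _scan_bilayer(curve, template, pv, k):
    """Grid scan over the bilayer envelope parameters (z_H1, sigma_H1,
    rho_r, sigma_C) with the linear subspace solved per candidate.

    The squared bilayer form factor shapes the mid/high-angle envelope;
    its minima positions trap gradient descent at the z_H bounds when
    the start is poor.  Fixed parameters keep their current value."""
    names = [f"c{k}.{f}" for f in ("z_H1", "sigma_H1", "rho_r", "sigma_C")]
    if names[0] not in pv or not pv[names[0]].free:
        return pv
    model, comp, nu_k, rest = _component_context(curve, template, pv, k)
    if nu_k <= 0:
        return pv
    s = curve.s
    chi2_now = objective(pv, curve, template)

    def grid(name, n):
        if name in pv and pv[name].free:
            p = pv[name]
            return list(np.linspace(p.lower, p.upper, n)) + [p.value]
        return [pv.value(name)] if name in pv else [None]

    z_g = grid(names[0], 13)
    sh_g = grid(names[1], 5)
    rr_g = grid(names[2], 6)
    sc_g = grid(names[3], 6)
    lam = comp.lamellar
    weight_names = [f"c{k}.w{L}" for _, L in lam.states]
    weights_free = any(n in pv and pv[n].free for n in weight_names)
    if weights_free and not lam.is_unilamellar:
        S_cols = [forward.mct_structure_factor(s, lam, L) for _, L in lam.states]
    else:
        wt = lam.normalized_weights()
        sf = np.zeros_like(s)
        for w_i, (_, L) in zip(wt, lam.states):
            sf += w_i * forward.mct_structure_factor(s, lam, L)
        S_cols = [sf]
    G = forward._size_averaged_shell(s, comp.size, template.n_nodes)
    base = nu_k * G
    bil0 = comp.bilayer
    dof = max(len(curve) - template.n_free, 1)
    best = (np.inf, None, None)
    for z in z_g:
        for sh in sh_g:
            for rr in rr_g:
                for sc in sc_g:
                    if template.symmetric_bilayer:
                        bil = BilayerParams(
                            z_H1=z, sigma_H1=sh, A2_over_A1=1.0,
                            z_H2=z, sigma_H2=sh, rho_r=rr, sigma_C=sc,
                        )
                    else:
                        bil = dataclasses.replace(
                            bil0, z_H1=z, sigma_H1=sh, rho_r=rr, sigma_C=sc
                        )
                    F2 = forward.bilayer_form_factor(s, bil) ** 2
                    cols = [base * F2 * Si for Si in S_cols]
                    coeffs, chi2 = _nnls_candidate(
                        cols, rest, curve, template.fit_background
                    )
                    chi2 /= dof
                    if chi2 < best[0]:
                        best = (chi2, (z, sh, rr, sc),
                                coeffs if weights_free else None)
    _, vals, coeffs = best
    updates = {
        n: v for n, v in zip(names, vals) if n in pv and pv[n].free
    }
    trial = pv.with_values(updates, clip=True)
    if coeffs is not None and not lam.is_unilamellar:
        tlam = template.build(trial).components[k].lamellar
        trial = trial.with_values(
            _weights_from_coeffs(trial, k, tlam.states, coeffs), clip=True
        )
    if objective(trial, curve, template) <= chi2_now:
        return trial
    return pv


def _scan_lamellar(curve, template, pv, k, n_d=41):
    """Joint (repeat distance, Caille parameter) preconditioning scan
    with the weight subspace solved per candidate."""
    name_d, name_e = f"c{k}.d", f"c{k}.eta"
    if name_d not in pv or not pv[name_d].free:
        return pv
    p_d = pv[name_d]
    ds = np.linspace(p_d.lower, p_d.upper, n_d)
    if name_e in pv and pv[name_e].free:
        candidates = [{name_d: d, name_e: e} for d in ds for e in _SCAN_ETAS]
    else:
        candidates = [{name_d: d} for d in ds]
    candidates.append({})  # incumbent
    return _scan_linear(curve, template, pv, k, candidates)


def fit(
    curve: ScatteringCurve,
    template: ModelTemplate,
    x0: Optional[Mapping[str, float]] = None,
    max_iter: int = 300,
    seed: Optional[int] = None,
    ftol: float = 1e-12,
    gtol: float = 1e-7,
    precondition: bool = True,
    polish_rounds: int = 4,
    max_cycles: int = 3,
    rescue_chi2: float = 10.0,
) -> FitResult:
    """Bounded quasi-Newton minimization of the reduced chi-square over
    the template's free parameters.

    The core step is L-BFGS-B in box-normalized coordinates with
    analytic gradients, restarted up to ``polish_rounds`` times while
    the chi-square keeps improving.  With ``precondition`` the step is
    wrapped in up to ``max_cycles`` basin-correction cycles: each cycle
    re-scans the multimodal directions (a joint radius/polydispersity
    grid, the headgroup centres and the lamellar repeat distances) at
    the current solution, re-minimizes, and stops once the chi-square
    improves by less than 1%.  Scans always include the incumbent
    value, so a start at the optimum is never degraded.  Deterministic
    given identical inputs.  Non-convergence flags the result instead
    of raising.
    """
    if curve.err is None:
        raise ParameterDomainError("curve must carry intensity errors for fitting")
    pv0 = template.initial_parameters()
    if x0 is not None:
        pv0 = pv0.with_values(dict(x0), clip=True)
    n_comp = len(template.model.components)
    n_iter_total = 0

    def minimize_polished(pv_in):
        nonlocal n_iter_total
        pv_b, chi2_b, ok_b, nit, msg_b = _minimize_once(
            curve, template, pv_in, max_iter, ftol, gtol
        )
        n_iter_total += nit
        for _ in range(polish_rounds - 1):
            prev = chi2_b
            pv2, chi2_2, ok2, nit, msg2 = _minimize_once(
                curve, template, pv_b, max_iter, ftol, gtol
            )
            n_iter_total += nit
            if chi2_2 < chi2_b:
                pv_b, chi2_b, ok_b, msg_b = pv2, chi2_2, ok2, msg2
            elif ok2 and not ok_b:
                # re-run from the same point certified convergence
                ok_b, msg_b = ok2, msg2
            if prev - chi2_b < 1e-6 * max(prev, 1e-30):
                break
        return pv_b, chi2_b, ok_b, msg_b

    def rescan(pv_in):
        for k in range(n_comp):
            pv_in = _scan_joint(curve, template, pv_in, k)
            pv_in = _scan_bilayer(curve, template, pv_in, k)
            pv_in = _scan_parameter(curve, template, pv_in, f"c{k}.z_H2", 41)
            pv_in = _scan_lamellar(curve, template, pv_in, k)
        return pv_in

    def run_cycles(pv_in):
        p = pv_in
        for k in range(n_comp):
            p = _scan_lamellar(curve, template, p, k)
            p = _scan_size(curve, template, p, k)
            p = _scan_bilayer(curve, template, p, k)
            p = _scan_lamellar(curve, template, p, k)
        p, c2, ok, m = minimize_polished(p)
        for _ in range(max_cycles - 1):
            p_c = rescan(p)
            p_c, c2_c, ok_c, m_c = minimize_polished(p_c)
            if c2_c < c2:
                p, ok, m = p_c, ok_c, m_c
                improved = (c2 - c2_c) > 0.01 * c2
                c2 = c2_c
                if not improved:
                    break
            else:
                if c2_c == c2 and ok_c and not ok:
                    ok, m = ok_c, m_c
                break
        return p, c2, ok, m

    if precondition and pv0.n_free > 0:
        pv, chi2, success, msg = run_cycles(pv0)
        if chi2 > rescue_chi2:
            # jointly wrong bilayer and lamellar structure can lock each
            # other in: retry from the current size with the structural
            # parameters reset to the middle of their bounds
            neutral = {}
            for p in pv:
                if not p.free:
                    continue
                field = p.name.split(".", 1)[1]
                if field.startswith("w"):
                    neutral[p.name] = 1.0
                elif field in ("z_H1", "z_H2", "sigma_H1", "sigma_H2",
                               "rho_r", "sigma_C", "A2_over_A1", "d", "eta"):
                    neutral[p.name] = 0.5 * (p.lower + p.upper)
            pv_r, chi2_r, success_r, msg_r = run_cycles(
                pv.with_values(neutral, clip=True)
            )
            if chi2_r < chi2:
                pv, chi2, success, msg = pv_r, chi2_r, success_r, msg_r
    else:
        pv, chi2, success, msg = minimize_polished(pv0)
    chi2, c, b, A, _ = _objective_parts(pv, curve, template, with_grad=False)
    model = dataclasses.replace(template.build(pv), scale=c, background=b)
    model_curve = ScatteringCurve(s=curve.s, I=c * A + b)
    return FitResult(
        parameters=pv,
        chi2_reduced=chi2,
        model=model,
        model_curve=model_curve,
        converged=success,
        n_free=template.n_free,
        n_iterations=n_iter_total,
        termination=msg,
        seed=seed,
    )


def fit_with_initialization(
    curve: ScatteringCurve,
    template: ModelTemplate,
    use_guinier: bool = True,
    **fit_kwargs,
) -> FitResult:
    """Like :func:`fit` but first replaces the starting mean radius of a
    single-population model by the Guinier radius of gyration (a thin
    shell has Rg close to its radius).  Falls back silently to the
    template start when no valid Guinier range exists."""
    x0 = dict(fit_kwargs.pop("x0", None) or {})
    if use_guinier and len(template.model.components) == 1:
        pv = template.initial_parameters()
        if "c0.R" in pv and pv["c0.R"].free and "c0.R" not in x0:
            try:
                rg, _ = guinier_rg(curve)
            except InitializationError:
                pass
            else:
                p = pv["c0.R"]
                x0["c0.R"] = float(np.clip(rg, p.lower, p.upper))
    return fit(curve, template, x0=x0 or None, **fit_kwargs)


def _perturbed_start(
    pv: ParameterVector, rng: np.random.Generator, amount: float
) -> Dict[str, float]:
    """Free values multiplied by (1 + U(-amount, amount)), clipped to
    bounds; parameters at zero are nudged additively within bounds."""
    start = {}
    for p in pv:
        if not p.free:
            continue
        if abs(p.value) > 1e-12:
            v = p.value * (1.0 + rng.uniform(-amount, amount))
        else:
            v = p.value + rng.uniform(-amount, amount) * (p.upper - p.lower)
        start[p.name] = float(np.clip(v, p.lower, p.upper))
    return start


def estimate_errors(
    curve: ScatteringCurve,
    template: ModelTemplate,
    n_restarts: int = 10,
    seed: int = 0,
    best: Optional[FitResult] = None,
    perturbation: float = 0.4,
    keep_factor: float = 1.05,
    max_iter: int = 300,
) -> FitResult:
    """Restart-ensemble parameter uncertainties.

    Re-fits from ``n_restarts`` randomized starts (free parameters
    perturbed by up to ``+-perturbation`` around the best fit, clipped
    to bounds), keeps converged runs whose chi-square is within
    ``keep_factor`` of the best, and reports the per-parameter standard
    deviation over the kept ensemble.  With fewer than 3 successful
    restarts the errors are reported as unavailable (``None``).
    """
    if best is None:
        best = fit(curve, template, seed=seed, max_iter=max_iter)
    rng = np.random.default_rng(seed)
    ensemble: List[ParameterVector] = [best.parameters]
    for _ in range(n_restarts):
        start = _perturbed_start(best.parameters, rng, perturbation)
        r = fit(curve, template, x0=start, seed=seed, max_iter=max_iter)
        # absolute slack keeps the criterion meaningful for noiseless
        # fixtures where the best chi-square is ~0
        if r.converged and r.chi2_reduced <= keep_factor * best.chi2_reduced + 1e-8:
            ensemble.append(r.parameters)
    n_ok = len(ensemble) - 1
    if n_ok < 3:
        errors = None
    else:
        errors = {}
        for name in best.parameters.free_names:
            vals = np.array([p.value(name) for p in ensemble])
            errors[name] = float(np.std(vals, ddof=1))
    return dataclasses.replace(best, param_errors=errors, n_restarts_converged=n_ok)


# -- lamellarity screening ---------------------------------------------------

def lamellarity_ladder(
    max_lamellarity: int, d: float = 6.5, eta: float = 0.1
) -> LamellarOrganization:
    """Hypothesis with equal-weight states L = 1 .. max_lamellarity."""
    if max_lamellarity < 1:
        raise ParameterDomainError("max_lamellarity must be >= 1")
    if max_lamellarity == 1:
        return LamellarOrganization.suv()
    w = 1.0 / max_lamellarity
    states = tuple((w, L) for L in range(1, max_lamellarity + 1))
    return LamellarOrganization(states=states, d=d, eta=eta)


def screen_models(
    curve: ScatteringCurve,
    base_model: MixtureModel,
    candidates: Sequence[LamellarOrganization],
    seed: Optional[int] = None,
    chi2_rel_tol: float = 0.05,
    max_iter: int = 300,
    template_kwargs: Optional[Mapping] = None,
) -> List[FitResult]:
    """Fit one model per lamellar-organization hypothesis and rank them.

    Each candidate replaces the lamellar organization of every component
    of ``base_model``; an independent fit is run per hypothesis.
    Results are ranked by reduced chi-square, with hypotheses whose
    chi-square lies within ``chi2_rel_tol`` of the best treated as ties
    and ordered by number of free parameters (parsimony).  The selected
    hypothesis is the first element.
    """
    if not candidates:
        raise ParameterDomainError("candidate hypothesis list must not be empty")
    kwargs = dict(template_kwargs or {})
    results: List[FitResult] = []
    for org in candidates:
        comps = tuple(
            dataclasses.replace(c, lamellar=org) for c in base_model.components
        )
        model = dataclasses.replace(base_model, components=comps)
        tmpl = ModelTemplate(model, **kwargs)
        r = fit(curve, tmpl, seed=seed, max_iter=max_iter)
        r.hypothesis = org
        results.append(r)
    best_chi2 = min(r.chi2_reduced for r in results)
    cut = best_chi2 * (1.0 + chi2_rel_tol)

    def key(r: FitResult):
        within = r.chi2_reduced <= cut
        return (0 if within else 1, r.n_free if within else 0, r.chi2_reduced)

    return sorted(results, key=key)
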