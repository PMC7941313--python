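"""Synthetic SAXS curve generation.

Provides the noise model (relative Gaussian noise, the large-count
limit of relative Poisson counting error) and the three-case SUV/MLV
validation suite used throughout the tests: (i) SUVs only, (ii) SUVs
plus MLVs with up to three ordered bilayers, (iii) SUVs plus MLVs with
up to seven ordered bilayers, all with 50 nm mean radius, 10%
polydispersity, a symmetric bilayer profile of 6.5 nm overall
thickness, Caille parameter 0.10 and 5% relative noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from . import forward
from .errors import ParameterDomainError
from .models import (
    BilayerParams,
    LamellarOrganization,
    MixtureComponent,
    MixtureModel,
    ScatteringCurve,
    SchulzSizeDistribution,
)

__all__ = [
    "SimulationSpec",
    "simulate_curve",
    "benchmark_model",
    "benchmark_cases",
    "BENCHMARK_CASE_NAMES",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic curve."""

    model: MixtureModel
    s_min: float  # nm^-1
    s_max: float  # nm^-1
    n_points: int
    grid: str = "logarithmic"  # or "linear"
    rel_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.s_min < self.s_max:
            raise ParameterDomainError("need 0 < s_min < s_max")
        if self.n_points < 2:
            raise ParameterDomainError("n_points must be >= 2")
        if self.rel_error < 0:
            raise ParameterDomainError("rel_error must be non-negative")
        if self.grid not in ("linear", "logarithmic"):
            raise ParameterDomainError("grid must be 'linear' or 'logarithmic'")

    def s_grid(self) -> np.ndarray:
        if self.grid == "linear":
            return np.linspace(self.s_min, self.s_max, self.n_points)
        return np.geomspace(self.s_min, self.s_max, self.n_points)


def simulate_curve(spec: SimulationSpec) -> ScatteringCurve:
    """Evaluate the model on the grid and add relative Gaussian noise.

    ``I_noisy = I_model * (1 + rel_error * g)`` with ``g`` standard
    normal draws from the spec's seed; the stored uncertainty is
    ``rel_error * I_model``.  Deterministic per seed.  With
    ``rel_error = 0`` the exact model curve is returned (no error
    column).
    """
    s = spec.s_grid()
    I_model = forward.mixture_intensity(s, spec.model).I
    if spec.rel_error == 0:
        return ScatteringCurve(s=s, I=I_model)
    rng = np.random.default_rng(spec.seed)
    g = rng.standard_normal(s.size)
    I_noisy = I_model * (1.0 + spec.rel_error * g)
    err = spec.rel_error * I_model
    return ScatteringCurve(s=s, I=I_noisy, err=err)


# -- three-case SUV/MLV validation suite -------------------------------------

BENCHMARK_CASE_NAMES = ("suv", "mlv3", "mlv7")

_BENCH_R = 50.0
_BENCH_SIGMA = 5.0
_BENCH_SIGMA_H = 0.3
_BENCH_THICKNESS = 6.5
_BENCH_RHO_R = 1.5
_BENCH_SIGMA_C = 0.45
_BENCH_D = 6.5
_BENCH_ETA = 0.10

# Occupancy weights of the lamellarity states L = 1..max for each case;
# substantial weight on the top state makes lamellarity identifiable.
_BENCH_WEIGHTS = {
    1: (1.0,),
    3: (0.5, 0.2, 0.3),
    7: (0.35, 0.05, 0.05, 0.05, 0.05, 0.1, 0.35),
}


def benchmark_bilayer() -> BilayerParams:
    """Symmetric five-Gaussian profile with overall thickness 6.5 nm.

    Thickness is defined as ``2 (z_H,outer + 2 sigma_H,outer)``; with
    sigma_H = 0.3 nm this puts the headgroup centres at 2.65 nm.
    """
    z_h = _BENCH_THICKNESS / 2.0 - 2.0 * _BENCH_SIGMA_H
    return BilayerParams(
        z_H1=z_h,
        sigma_H1=_BENCH_SIGMA_H,
        A2_over_A1=1.0,
        z_H2=z_h,
        sigma_H2=_BENCH_SIGMA_H,
        rho_r=_BENCH_RHO_R,
        sigma_C=_BENCH_SIGMA_C,
    )


def benchmark_model(max_lamellarity: int = 7) -> MixtureModel:
    """Ground-truth single-population mixture of the validation suite."""
    if max_lamellarity not in _BENCH_WEIGHTS:
        raise ParameterDomainError(
            f"max_lamellarity must be one of {sorted(_BENCH_WEIGHTS)}"
        )
    weights = _BENCH_WEIGHTS[max_lamellarity]
    if max_lamellarity == 1:
        lam = LamellarOrganization.suv()
    else:
        states = tuple((w, L) for L, w in enumerate(weights, start=1))
        lam = LamellarOrganization(states=states, d=_BENCH_D, eta=_BENCH_ETA)
    comp = MixtureComponent(
        nu=1.0,
        size=SchulzSizeDistribution(R=_BENCH_R, sigma=_BENCH_SIGMA),
        bilayer=benchmark_bilayer(),
        lamellar=lam,
    )
    return MixtureModel(components=(comp,))


def benchmark_spec(max_lamellarity: int, seed: int = 0,
                   rel_error: float = 0.05) -> SimulationSpec:
    """Simulation recipe for one validation case (log grid over the
    typical measured range, 5% relative noise)."""
    return SimulationSpec(
        model=benchmark_model(max_lamellarity),
        s_min=0.01,
        s_max=7.0,
        n_points=400,
        grid="logarithmic",
        rel_error=rel_error,
        seed=seed,
    )


def benchmark_cases(seed: int = 0) -> Dict[str, Tuple[ScatteringCurve, MixtureModel]]:
    """The three validation cases as ``name -> (noisy curve, truth)``."""
    out: Dict[str, Tuple[ScatteringCurve, MixtureModel]] = {}
    for name, lmax in zip(BENCHMARK_CASE_NAMES, (1, 3, 7)):
        spec = benchmark_spec(lmax, seed=seed)
        out[name] = (simulate_curve(spec), spec.model)
    return out
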