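"""Domain types for vesicle mixture scattering models.

Internal units are nanometres for lengths and inverse nanometres for
momentum transfer ``s = 4 pi sin(theta) / lambda``.  Intensities are in
arbitrary units; the absolute level is carried by ``MixtureModel.scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .errors import ParameterDomainError

__all__ = [
    "ScatteringCurve",
    "BilayerParams",
    "SchulzSizeDistribution",
    "LamellarOrganization",
    "MixtureComponent",
    "MixtureModel",
]


@dataclass(frozen=True)
class ScatteringCurve:
    """A 1-D scattering curve: momentum-transfer grid, intensities and
    optional 1-sigma uncertainties.

    Parameters
    ----------
    s : array-like
        Momentum transfer in nm^-1, strictly increasing and positive.
    I : array-like
        Intensity, arbitrary units, same length as ``s``.
    err : array-like, optional
        1-sigma uncertainty of ``I``; strictly positive if present.
        Model curves typically carry no errors.
    """

    s: np.ndarray
    I: np.ndarray
    err: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "I", I)
        if s.ndim != 1 or s.size < 1:
            raise ParameterDomainError("s must be a non-empty 1-D array")
        if I.shape != s.shape:
            raise ParameterDomainError("I must have the same shape as s")
        if np.any(s <= 0):
            raise ParameterDomainError("all s values must be positive")
        if np.any(np.diff(s) <= 0):
            raise ParameterDomainError("s must be strictly increasing")
        if self.err is not None:
            err = np.asarray(self.err, dtype=float)
            object.__setattr__(self, "err", err)
            if err.shape != I.shape:
                raise ParameterDomainError("err must have the same shape as I")
            if np.any(err <= 0):
                raise ParameterDomainError("all err values must be positive")

    def __len__(self) -> int:
        return self.s.size


@dataclass(frozen=True)
class BilayerParams:
    """Five-Gaussian transbilayer electron density parameterization.

    The profile is built from two mirrored headgroup Gaussian pairs at
    ``+-z_H1`` (amplitude ``A1``, width ``sigma_H1``) and ``+-z_H2``
    (amplitude ``A2 = A2_over_A1 * A1``, width ``sigma_H2``) plus one
    central hydrocarbon Gaussian of amplitude ``-rho_r * A1`` and width
    ``sigma_C``.  ``A1`` is a fixed gauge (profiles are relative; the
    absolute level is absorbed by the mixture scale), so the only free
    amplitude shape parameter is ``A2_over_A1``.  ``rho_r`` is stored
    positive; the negative sign of the hydrocarbon trough is applied
    inside the model.
    """

    z_H1: float
    sigma_H1: float
    A2_over_A1: float
    z_H2: float
    sigma_H2: float
    rho_r: float
    sigma_C: float
    A1: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_H1 <= 0 or self.sigma_H2 <= 0 or self.sigma_C <= 0:
            raise ParameterDomainError("all Gaussian widths must be positive")
        if self.z_H1 <= 0 or self.z_H2 <= 0:
            raise ParameterDomainError("headgroup centres must be positive")
        if self.A2_over_A1 <= 0:
            raise ParameterDomainError("A2_over_A1 must be positive")
        if self.rho_r <= 0:
            raise ParameterDomainError("rho_r must be positive")
        if self.A1 <= 0:
            raise ParameterDomainError("A1 must be positive")

    @property
    def outer_pair(self) -> Tuple[float, float]:
        """(z_H, sigma_H) of the outermost headgroup Gaussian pair."""
        if self.z_H1 >= self.z_H2:
            return self.z_H1, self.sigma_H1
        return self.z_H2, self.sigma_H2

    @property
    def thickness(self) -> float:
        """Overall bilayer thickness, ``2 * (z_H,outer + 2 sigma_H,outer)``.

        Convention: the bilayer is taken to extend two Gaussian widths
        past the outermost headgroup centre on each side.
        """
        z, sig = self.outer_pair
        return 2.0 * (z + 2.0 * sig)


@dataclass(frozen=True)
class SchulzSizeDistribution:
    """Monomodal Schulz (gamma-family) vesicle size distribution with
    mean radius ``R`` and standard deviation ``sigma`` (both nm)."""

    R: float
    sigma: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ParameterDomainError("mean radius R must be positive")
        if self.sigma <= 0:
            raise ParameterDomainError("width sigma must be positive")
        if self.sigma > 0.5 * self.R:
            raise ParameterDomainError(
                f"polydispersity sigma/R = {self.sigma / self.R:.3f} exceeds 0.5"
            )

    @property
    def polydispersity(self) -> float:
        return self.sigma / self.R

    @property
    def shape(self) -> float:
        """Gamma shape parameter k = (R/sigma)^2 (Schulz z = k - 1)."""
        return (self.R / self.sigma) ** 2

    @property
    def scale(self) -> float:
        """Gamma scale parameter theta = sigma^2 / R."""
        return self.sigma**2 / self.R


@dataclass(frozen=True)
class LamellarOrganization:
    """Occupancy-weighted lamellarity states of a vesicle population.

    ``states`` is a list of ``(w_i, L_i)`` pairs: occupancy weight and
    integer number of ordered bilayers.  ``d`` is the lamellar repeat
    distance (nm) and ``eta`` the Caille fluctuation parameter; both are
    inert when all states are unilamellar.
    """

    states: Tuple[Tuple[float, int], ...]
    d: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        states = tuple((float(w), int(L)) for w, L in self.states)
        object.__setattr__(self, "states", states)
        if not states:
            raise ParameterDomainError("at least one lamellarity state required")
        if any(w < 0 for w, _ in states):
            raise ParameterDomainError("occupancy weights must be non-negative")
        if sum(w for w, _ in states) <= 0:
            raise ParameterDomainError("occupancy weights must not all vanish")
        Ls = [L for _, L in states]
        if any(L < 1 for L in Ls):
            raise ParameterDomainError("lamellarities must be >= 1")
        if len(set(Ls)) != len(Ls):
            raise ParameterDomainError("lamellarities must be distinct")
        if self.max_lamellarity >= 2:
            if self.d <= 0:
                raise ParameterDomainError("repeat distance d must be positive for MLV states")
            if self.eta < 0:
                raise ParameterDomainError("Caille parameter eta must be non-negative")

    @classmethod
    def suv(cls) -> "LamellarOrganization":
        """Pure single-unilamellar-vesicle organization."""
        return cls(states=((1.0, 1),))

    @property
    def max_lamellarity(self) -> int:
        return max(L for _, L in self.states)

    @property
    def is_unilamellar(self) -> bool:
        return self.max_lamellarity == 1

    def normalized_weights(self) -> np.ndarray:
        w = np.array([w for w, _ in self.states], dtype=float)
        return w / w.sum()

    def normalized(self) -> "LamellarOrganization":
        w = self.normalized_weights()
        states = tuple((float(wi), L) for wi, (_, L) in zip(w, self.states))
        return replace(self, states=states)


@dataclass(frozen=True)
class MixtureComponent:
    """One vesicle population: volume fraction, size distribution,
    bilayer density parameters and lamellar organization."""

    nu: float
    size: SchulzSizeDistribution
    bilayer: BilayerParams
    lamellar: LamellarOrganization = field(default_factory=LamellarOrganization.suv)

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ParameterDomainError("volume fraction nu must be non-negative")


@dataclass(frozen=True)
class MixtureModel:
    """N-component vesicle mixture with a global scale and an optional
    flat background (an extension over the pure mixture sum; default 0)."""

    components: Tuple[MixtureComponent, ...]
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        components = tuple(self.components)
        object.__setattr__(self, "components", components)
        if not components:
            raise ParameterDomainError("mixture must contain at least one component")
        if self.scale <= 0:
            raise ParameterDomainError("scale must be positive")
        if self.background < 0:
            raise ParameterDomainError("background must be non-negative")
        if sum(c.nu for c in components) <= 0:
            raise ParameterDomainError("volume fractions must not all vanish")

    def normalized_fractions(self) -> np.ndarray:
        nu = np.array([c.nu for c in self.components], dtype=float)
        return nu / nu.sum()
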