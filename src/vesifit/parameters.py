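"""Flat named parameter vectors with bounds and fixed/free flags."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, Iterator, List, Mapping

import numpy as np

from .errors import ParameterDomainError

__all__ = ["Parameter", "ParameterVector"]


@dataclass(frozen=True)
class Parameter:
    """One scalar model parameter: name, value, bounds, free flag."""

    name: str
    value: float
    lower: float = -np.inf
    upper: float = np.inf
    free: bool = True

    def __post_init__(self) -> None:
        if not self.lower <= self.value <= self.upper:
            raise ParameterDomainError(
                f"parameter {self.name}: value {self.value} outside "
                f"bounds [{self.lower}, {self.upper}]"
            )
        if self.free and not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ParameterDomainError(
                f"free parameter {self.name} must have finite bounds"
            )
        if self.free and self.upper <= self.lower:
            raise ParameterDomainError(
                f"free parameter {self.name} has an empty bound interval"
            )


class ParameterVector:
    """Ordered collection of named :class:`Parameter` objects.

    Immutable in style: updates return new vectors.  Fixed parameters
    are carried along but excluded from the free-value interface used
    by the optimizer.
    """

    def __init__(self, params: Iterable[Parameter]):
        self._params: List[Parameter] = list(params)
        names = [p.name for p in self._params]
        if len(set(names)) != len(names):
            raise ParameterDomainError("duplicate parameter names")
        self._index: Dict[str, int] = {n: i for i, n in enumerate(names)}

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> Parameter:
        return self._params[self._index[name]]

    def value(self, name: str) -> float:
        return self[name].value

    @property
    def names(self) -> List[str]:
        return [p.name for p in self._params]

    @property
    def free_names(self) -> List[str]:
        return [p.name for p in self._params if p.free]

    @property
    def n_free(self) -> int:
        return sum(p.free for p in self._params)

    def free_values(self) -> np.ndarray:
        return np.array([p.value for p in self._params if p.free], dtype=float)

    def free_bounds(self) -> np.ndarray:
        """(n_free, 2) array of lower/upper bounds."""
        return np.array(
            [(p.lower, p.upper) for p in self._params if p.free], dtype=float
        )

    def values(self) -> Dict[str, float]:
        return {p.name: p.value for p in self._params}

    def with_free_values(self, x: np.ndarray) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        if x.size != self.n_free:
            raise ParameterDomainError(
                f"expected {self.n_free} free values, got {x.size}"
            )
        out, j = [], 0
        for p in self._params:
            if p.free:
                out.append(replace(p, value=float(np.clip(x[j], p.lower, p.upper))))
                j += 1
            else:
                out.append(p)
        return ParameterVector(out)

    def with_values(self, updates: Mapping[str, float], clip: bool = False) -> "ParameterVector":
        out = []
        for p in self._params:
            if p.name in updates:
                v = float(updates[p.name])
                if clip:
                    v = float(np.clip(v, p.lower, p.upper))
                out.append(replace(p, value=v))
            else:
                out.append(p)
        unknown = set(updates) - set(self._index)
        if unknown:
            raise ParameterDomainError(f"unknown parameter names: {sorted(unknown)}")
        return ParameterVector(out)

    def __repr__(self) -> str:
        rows = ", ".join(
            f"{p.name}={p.value:.6g}{'' if p.free else ' (fixed)'}" for p in self._params
        )
        return f"ParameterVector({rows})"
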