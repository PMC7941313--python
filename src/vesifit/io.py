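"""Reading/writing scattering curves, model configuration files and
human-readable result reports.

Curves travel as 3-column ASCII ``.dat`` files (s, I, err) with ``#``
comment lines.  Model configurations are flat YAML documents describing
the mixture components, per-parameter bounds/fixed flags and fit
options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from . import forward
from .errors import ConfigError, FormatError
from .fitting import FitResult, ModelTemplate
from .models import (
    BilayerParams,
    LamellarOrganization,
    MixtureComponent,
    MixtureModel,
    ScatteringCurve,
    SchulzSizeDistribution,
)
from .simulate import SimulationSpec

logger = logging.getLogger("vesifit.io")

__all__ = [
    "read_dat",
    "write_dat",
    "ModelConfig",
    "read_config",
    "write_config",
    "export_profile",
    "export_distribution",
    "format_report",
    "report",
]

UNITS = ("nm_inv", "angstrom_inv")


# -- curves ------------------------------------------------------------------

def read_dat(path, units: str = "nm_inv") -> ScatteringCurve:
    """Read a 3-column (s, I, err) ASCII curve.

    ``#``-prefixed lines and non-numeric header lines are skipped.
    ``units='angstrom_inv'`` converts s to nm^-1 (x10).  Rows with
    non-positive s, I or err are dropped (count logged).  A missing
    error column is replaced by 1% of I with a warning.
    """
    if units not in UNITS:
        raise FormatError(f"unknown units {units!r}; expected one of {UNITS}")
    rows: List[Tuple[float, ...]] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            try:
                vals = tuple(float(x) for x in parts[:3])
            except ValueError:
                continue  # header / footer text
            if len(vals) >= 2:
                rows.append(vals)
    if not rows:
        raise FormatError(f"no parseable data rows in {path}")
    n_cols = min(len(r) for r in rows)
    data = np.array([r[:n_cols] for r in rows], dtype=float)
    s, I = data[:, 0], data[:, 1]
    if n_cols >= 3:
        err = data[:, 2]
    else:
        logger.warning("%s: no error column; assuming 1%% of I", path)
        err = 0.01 * np.abs(I)
    if units == "angstrom_inv":
        s = s * 10.0
    keep = (s > 0) & (I > 0) & (err > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("%s: dropped %d non-positive rows", path, n_drop)
    if not keep.any():
        raise FormatError(f"no valid data rows in {path}")
    order = np.argsort(s[keep], kind="stable")
    return ScatteringCurve(s=s[keep][order], I=I[keep][order], err=err[keep][order])


def write_dat(curve: ScatteringCurve, path, header: str = "") -> None:
    """Write a curve as 3-column ASCII (2 columns if no errors)."""
    cols = [curve.s, curve.I]
    names = "s(1/nm) I"
    if curve.err is not None:
        cols.append(curve.err)
        names += " err"
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# {names}\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v: .10e}" for v in row) + "\n")


# -- model configuration -----------------------------------------------------

@dataclass
class ModelConfig:
    """Declarative mixture-model description parsed from YAML."""

    model: MixtureModel
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    fixed: List[str] = field(default_factory=list)
    fit_options: Dict[str, object] = field(default_factory=dict)
    simulate_options: Optional[Dict[str, object]] = None
    units: str = "nm_inv"

    def template(self, **overrides) -> ModelTemplate:
        """ModelTemplate bound to this configuration."""
        kwargs = dict(
            symmetric_bilayer=bool(self.fit_options.get("symmetric_bilayer", False)),
            fit_weights=bool(self.fit_options.get("fit_weights", True)),
            fit_background=bool(self.fit_options.get("fit_background", False)),
            bounds=self.bounds,
            fixed=self.fixed,
        )
        kwargs.update(overrides)
        return ModelTemplate(self.model, **kwargs)

    def simulation_spec(self, seed: Optional[int] = None) -> SimulationSpec:
        if self.simulate_options is None:
            raise ConfigError("configuration has no 'simulate' section")
        opts = dict(self.simulate_options)
        if seed is not None:
            opts["seed"] = int(seed)
        return SimulationSpec(model=self.model, **opts)


_PARAM_KEYS = {"value", "min", "max", "fixed"}


def _leaf(node, name: str, cfg_bounds: dict, cfg_fixed: list) -> float:
    """Parse a scalar-or-mapping parameter leaf, collecting bound and
    fixed-flag overrides under the flat parameter name."""
    if isinstance(node, (int, float)):
        return float(node)
    if isinstance(node, Mapping):
        unknown = set(node) - _PARAM_KEYS
        if unknown:
            raise ConfigError(f"parameter {name}: unknown keys {sorted(unknown)}")
        if "value" not in node:
            raise ConfigError(f"parameter {name}: missing 'value'")
        lo = node.get("min")
        hi = node.get("max")
        if (lo is None) != (hi is None):
            raise ConfigError(f"parameter {name}: specify both min and max or neither")
        if lo is not None:
            cfg_bounds[name] = (float(lo), float(hi))
        if node.get("fixed", False):
            cfg_fixed.append(name)
        return float(node["value"])
    raise ConfigError(f"parameter {name}: expected number or mapping, got {type(node).__name__}")


def _require_keys(node: Mapping, allowed: set, context: str) -> None:
    unknown = set(node) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")


_TOP_KEYS = {"units", "scale", "background", "fit", "simulate", "components"}
_COMP_KEYS = {"nu", "size", "bilayer", "lamellar"}
_SIZE_KEYS = {"R", "sigma"}
_BILAYER_KEYS = {"z_H1", "sigma_H1", "A2_over_A1", "z_H2", "sigma_H2", "rho_r", "sigma_C"}
_LAM_KEYS = {"d", "eta", "states"}
_STATE_KEYS = {"L", "w"}
_FIT_KEYS = {
    "max_iter", "restarts", "seed", "symmetric_bilayer", "fit_weights",
    "fit_background",
}
_SIM_KEYS = {"s_min", "s_max", "n_points", "grid", "rel_error", "seed"}


def parse_config(doc: Mapping) -> ModelConfig:
    """Build a :class:`ModelConfig` from a parsed YAML mapping.

    Unknown keys anywhere in the document are rejected.
    """
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration must be a mapping")
    _require_keys(doc, _TOP_KEYS, "top level")
    units = doc.get("units", "nm_inv")
    if units not in UNITS:
        raise ConfigError(f"units must be one of {UNITS}")
    bounds: Dict[str, Tuple[float, float]] = {}
    fixed: List[str] = []
    comps_doc = doc.get("components")
    if not comps_doc:
        raise ConfigError("configuration must define at least one component")
    components = []
    for k, cnode in enumerate(comps_doc):
        _require_keys(cnode, _COMP_KEYS, f"components[{k}]")
        pre = f"c{k}."
        nu = _leaf(cnode.get("nu", 1.0), pre + "nu", bounds, fixed)
        size_doc = cnode.get("size")
        if not isinstance(size_doc, Mapping):
            raise ConfigError(f"components[{k}]: missing 'size' section")
        _require_keys(size_doc, _SIZE_KEYS, f"components[{k}].size")
        size = SchulzSizeDistribution(
            R=_leaf(size_doc["R"], pre + "R", bounds, fixed),
            sigma=_leaf(size_doc["sigma"], pre + "sigma", bounds, fixed),
        )
        bil_doc = cnode.get("bilayer")
        if not isinstance(bil_doc, Mapping):
            raise ConfigError(f"components[{k}]: missing 'bilayer' section")
        _require_keys(bil_doc, _BILAYER_KEYS, f"components[{k}].bilayer")
        bkw = {}
        for key in _BILAYER_KEYS:
            if key in bil_doc:
                bkw[key] = _leaf(bil_doc[key], pre + key, bounds, fixed)
        for key, alias in (("z_H2", "z_H1"), ("sigma_H2", "sigma_H1")):
            bkw.setdefault(key, bkw.get(alias))
        bkw.setdefault("A2_over_A1", 1.0)
        missing = {"z_H1", "sigma_H1", "rho_r", "sigma_C"} - set(bkw)
        if missing:
            raise ConfigError(f"components[{k}].bilayer: missing {sorted(missing)}")
        bilayer = BilayerParams(**bkw)
        lam_doc = cnode.get("lamellar")
        if lam_doc is None:
            lamellar = LamellarOrganization.suv()
        else:
            _require_keys(lam_doc, _LAM_KEYS, f"components[{k}].lamellar")
            states_doc = lam_doc.get("states", [{"L": 1, "w": 1.0}])
            states = []
            for snode in states_doc:
                _require_keys(snode, _STATE_KEYS, f"components[{k}].lamellar.states")
                L = int(snode["L"])
                w = _leaf(snode.get("w", 1.0), pre + f"w{L}", bounds, fixed)
                states.append((w, L))
            lamellar = LamellarOrganization(
                states=tuple(states),
                d=_leaf(lam_doc.get("d", 0.0), pre + "d", bounds, fixed),
                eta=_leaf(lam_doc.get("eta", 0.0), pre + "eta", bounds, fixed),
            )
        components.append(
            MixtureComponent(nu=nu, size=size, bilayer=bilayer, lamellar=lamellar)
        )
    model = MixtureModel(
        components=tuple(components),
        scale=float(doc.get("scale", 1.0)),
        background=float(doc.get("background", 0.0)),
    )
    fit_options = dict(doc.get("fit") or {})
    _require_keys(fit_options, _FIT_KEYS, "fit")
    sim_options = doc.get("simulate")
    if sim_options is not None:
        sim_options = dict(sim_options)
        _require_keys(sim_options, _SIM_KEYS, "simulate")
    return ModelConfig(
        model=model,
        bounds=bounds,
        fixed=fixed,
        fit_options=fit_options,
        simulate_options=sim_options,
        units=units,
    )


def read_config(path) -> ModelConfig:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    return parse_config(doc)


def config_document(
    model: MixtureModel,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    fixed: Sequence[str] = (),
    fit_options: Optional[Mapping] = None,
    simulate_options: Optional[Mapping] = None,
    units: str = "nm_inv",
) -> dict:
    """Serialize a model (plus options) back into the config dialect."""
    bounds = dict(bounds or {})
    fixed = set(fixed)

    def leaf(name: str, value: float):
        entry: dict = {}
        if name in bounds:
            entry["min"], entry["max"] = (float(b) for b in bounds[name])
        if name in fixed:
            entry["fixed"] = True
        if entry:
            entry["value"] = float(value)
            return entry
        return float(value)

    comps = []
    for k, c in enumerate(model.components):
        pre = f"c{k}."
        b = c.bilayer
        cnode: dict = {
            "nu": leaf(pre + "nu", c.nu),
            "size": {
                "R": leaf(pre + "R", c.size.R),
                "sigma": leaf(pre + "sigma", c.size.sigma),
            },
            "bilayer": {
                key: leaf(pre + key, getattr(b, key)) for key in sorted(_BILAYER_KEYS)
            },
        }
        lam = c.lamellar
        lnode: dict = {
            "states": [{"L": L, "w": leaf(pre + f"w{L}", w)} for w, L in lam.states]
        }
        if not lam.is_unilamellar:
            lnode["d"] = leaf(pre + "d", lam.d)
            lnode["eta"] = leaf(pre + "eta", lam.eta)
        cnode["lamellar"] = lnode
        comps.append(cnode)
    doc: dict = {"units": units, "scale": float(model.scale),
                 "background": float(model.background), "components": comps}
    if fit_options:
        doc["fit"] = dict(fit_options)
    if simulate_options:
        doc["simulate"] = dict(simulate_options)
    return doc


def write_config(cfg_or_model: Union[ModelConfig, MixtureModel], path) -> None:
    if isinstance(cfg_or_model, ModelConfig):
        cfg = cfg_or_model
        doc = config_document(
            cfg.model, cfg.bounds, cfg.fixed, cfg.fit_options,
            cfg.simulate_options, cfg.units,
        )
    else:
        doc = config_document(cfg_or_model)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# -- exports -----------------------------------------------------------------

def export_profile(
    p: BilayerParams, path, z_max: Optional[float] = None, n_points: int = 401
) -> None:
    """Write the electron density profile rho(z) as a 2-column table on
    a symmetric grid."""
    if z_max is None:
        z_out, _ = p.outer_pair
        z_max = z_out + 4.0 * max(p.sigma_H1, p.sigma_H2, p.sigma_C)
    z = np.linspace(-z_max, z_max, n_points)
    rho = forward.bilayer_density(z, p)
    with open(path, "w") as fh:
        fh.write("# z(nm) rho(relative)\n")
        for zi, ri in zip(z, rho):
            fh.write(f"{zi: .10e} {ri: .10e}\n")


def export_distribution(
    dist: SchulzSizeDistribution, path, n_points: int = 801
) -> None:
    """Write the vesicle size distribution D_V(r) as a 2-column table
    over r in [max(0, R - 5 sigma), R + 5 sigma]."""
    lo = max(0.0, dist.R - 5.0 * dist.sigma)
    hi = dist.R + 5.0 * dist.sigma
    r = np.linspace(lo, hi, n_points)
    d = forward.schulz_density(r, dist)
    with open(path, "w") as fh:
        fh.write("# r(nm) D_V(1/nm)\n")
        for ri, di in zip(r, d):
            fh.write(f"{ri: .10e} {di: .10e}\n")


# -- report ------------------------------------------------------------------

def _fmt(value: float, err: Optional[float]) -> str:
    if err is None:
        return f"{value:.4g}"
    return f"{value:.4g} ± {err:.2g}"


def _organization_label(lam: LamellarOrganization) -> str:
    if lam.is_unilamellar:
        return "SUV"
    return f"SUV + MLV (up to {lam.max_lamellarity} layers)"


def format_report(
    model: MixtureModel,
    param_errors: Optional[Mapping[str, float]] = None,
    chi2_reduced: Optional[float] = None,
    title: str = "vesifit reconstruction",
) -> str:
    """Human-readable result table: bilayer parameters, size
    distribution, structural organization and derived quantities per
    component, with +- errors when a restart ensemble is available."""
    errs = dict(param_errors or {})

    def err_for(pre: str, *names: str) -> Optional[float]:
        for n in names:
            if pre + n in errs:
                return errs[pre + n]
        return None

    lines = [title, "=" * len(title), ""]
    nu = model.normalized_fractions()
    for k, comp in enumerate(model.components):
        pre = f"c{k}."
        b = comp.bilayer
        lam = comp.lamellar.normalized()
        lines.append(f"Component {k + 1} (volume fraction {nu[k]:.3f})")
        lines.append("Parameters of the lipid bilayer")
        lines.append(f"  z_H1 (nm)      {_fmt(b.z_H1, err_for(pre, 'z_H1'))}")
        lines.append(f"  sigma_H1 (nm)  {_fmt(b.sigma_H1, err_for(pre, 'sigma_H1'))}")
        lines.append(f"  A2/A1          {_fmt(b.A2_over_A1, err_for(pre, 'A2_over_A1'))}")
        lines.append(f"  z_H2 (nm)      {_fmt(b.z_H2, err_for(pre, 'z_H2', 'z_H1'))}")
        lines.append(f"  sigma_H2 (nm)  {_fmt(b.sigma_H2, err_for(pre, 'sigma_H2', 'sigma_H1'))}")
        lines.append(f"  rho_r          {_fmt(b.rho_r, err_for(pre, 'rho_r'))}")
        lines.append(f"  sigma_C (nm)   {_fmt(b.sigma_C, err_for(pre, 'sigma_C'))}")
        lines.append("Parameters of the MLV size distribution")
        lines.append(f"  R (nm)         {_fmt(comp.size.R, err_for(pre, 'R'))}")
        lines.append(f"  sigma (nm)     {_fmt(comp.size.sigma, err_for(pre, 'sigma'))}")
        lines.append("Structural organization")
        if lam.is_unilamellar:
            lines.append("  Caille parameter eta   -")
        else:
            lines.append(f"  Caille parameter eta   {_fmt(lam.eta, err_for(pre, 'eta'))}")
            lines.append(f"  Lamellar repeat distance d (nm)   {_fmt(lam.d, err_for(pre, 'd'))}")
            occ = ", ".join(f"L={L}: {w:.3f}" for w, L in lam.states)
            lines.append(f"  Occupancies   {occ}")
        lines.append(
            f"  Maximum number of ordered bilayers (SUV/MLV)   {_organization_label(lam)}"
        )
        lines.append("Derived quantities")
        lines.append(f"  Head-to-head distance d_HH (nm)   {forward.head_to_head_distance(b):.3f}")
        lines.append(f"  Bilayer thickness (nm)            {b.thickness:.3f}")
        lines.append(f"  Polydispersity sigma/R            {comp.size.polydispersity:.3f}")
        lines.append("")
    if chi2_reduced is not None:
        lines.append(f"Goodness of fit: reduced chi-square = {chi2_reduced:.4g}")
        lines.append("")
    return "\n".join(lines)


def report(result: FitResult, path=None, title: str = "vesifit reconstruction") -> str:
    """Format (and optionally write) the report for a fit result."""
    text = format_report(
        result.model,
        param_errors=result.param_errors,
        chi2_reduced=result.chi2_reduced,
        title=title,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
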