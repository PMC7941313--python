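# vesifit

Forward modelling and fitting of small-angle X-ray scattering (SAXS)
curves from polydisperse mixtures of single- and multi-lamellar lipid
vesicles (SUVs/MLVs).

The forward model combines, per vesicle population:

- a **separated form factor**: thin-spherical-shell factor (vesicle
  size) × flat-bilayer factor (transbilayer electron density),
- a **five-Gaussian electron density profile** — two mirrored headgroup
  Gaussian pairs plus a negative central hydrocarbon Gaussian
  (parameters `z_H1, sigma_H1, A2/A1, z_H2, sigma_H2, rho_r, sigma_C`),
- a **modified Caillé theory structure factor** for stacks of `L`
  ordered bilayers (repeat distance `d`, fluctuation parameter `eta`),
  mixed over an occupancy-weighted set of lamellarity states,
- a **Schulz (gamma) size distribution** with mean radius `R` and width
  `sigma`, integrated by fixed-node Gauss–Legendre quadrature.

The fitting engine minimizes the reduced chi-square with a bounded
quasi-Newton method (L-BFGS-B, analytic gradients, box-normalized
coordinates). The global intensity scale — and, because the model is
linear in them, the occupancy weights — are profiled out analytically
(weighted least squares / non-negative least squares), and the
multimodal directions (radius, headgroup position, repeat distance) are
preconditioned by joint grid scans, giving reliable convergence from
starting values as far as ±40% from the solution. Restart ensembles
provide per-parameter uncertainties; a screening driver ranks
lamellar-organization hypotheses by chi-square with a parsimony
tie-break.

Internal units: nm and nm⁻¹ (`s = 4π sinθ/λ`); curves recorded in Å⁻¹
are converted on read.

## Python API

```python
import numpy as np
from vesifit import (BilayerParams, LamellarOrganization, MixtureComponent,
                     MixtureModel, SchulzSizeDistribution,
                     SimulationSpec, simulate_curve, ModelTemplate, fit)

comp = MixtureComponent(
    nu=1.0,
    size=SchulzSizeDistribution(R=50.0, sigma=5.0),
    bilayer=BilayerParams(z_H1=2.0, sigma_H1=0.2, A2_over_A1=1.0,
                          z_H2=2.0, sigma_H2=0.2, rho_r=1.5, sigma_C=0.4),
    lamellar=LamellarOrganization(states=((0.6, 1), (0.4, 7)), d=6.5, eta=0.1),
)
model = MixtureModel(components=(comp,))
curve = simulate_curve(SimulationSpec(model, s_min=0.01, s_max=7.0,
                                      n_points=400, rel_error=0.05, seed=1))
result = fit(curve, ModelTemplate(model, symmetric_bilayer=True))
print(result.chi2_reduced, result.value("c0.R"))
```

## Command-line interface

The `vesifit` command exposes `simulate`, `fit`, `screen` and `report`
subcommands. Curves are 3-column ASCII `.dat` files (`s  I  err`, `#`
comments); models are YAML configs where every numeric parameter is
either a plain value or `{value, min, max, fixed}`:

```yaml
units: nm_inv
components:
  - nu: 1.0
    size:
      R: {value: 50.0, min: 20.0, max: 150.0}
      sigma: 5.0
    bilayer:
      z_H1: 2.0
      sigma_H1: 0.2
      rho_r: 1.5
      sigma_C: 0.4
    lamellar:
      d: 6.5
      eta: 0.1
      states:
        - {L: 1, w: 0.6}
        - {L: 7, w: 0.4}
fit:
  symmetric_bilayer: true
  restarts: 10
simulate:
  s_min: 0.01
  s_max: 7.0
  n_points: 400
  rel_error: 0.05
  seed: 1
```

```sh
vesifit simulate model.yaml -o curve.dat --seed 1
vesifit fit curve.dat model.yaml -o run1          # run1.report.txt, run1.fit.dat, ...
vesifit screen curve.dat model.yaml --lmax-min 1 --lmax-max 10 -o screen1
vesifit report model.yaml
```

Exit codes: `0` success, `1` input/configuration error, `2` fit did not
converge.

The report lists, per component, the bilayer parameters, the size
distribution (`R`, `sigma`), the structural organization (maximum
lamellarity, `d`, `eta`, occupancies) and derived quantities
(head-to-head distance `d_HH`, bilayer thickness `2(z_H + 2σ_H)`,
polydispersity), with `±` uncertainties from restart ensembles when
`restarts > 0`.

## Layout

- `src/vesifit/models.py` — domain types and invariants
- `src/vesifit/forward.py` — forward scattering model
- `src/vesifit/fitting.py` — objective, quasi-Newton engine, scans,
  error estimation, lamellarity screening
- `src/vesifit/simulate.py` — synthetic curves and the validation suite
- `src/vesifit/io.py`, `src/vesifit/cli.py` — `.dat`/YAML I/O, reports,
  CLI
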