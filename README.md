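# hpmono

High-order (p-version) hierarchical finite elements for the cardiac
monodomain equation with the Luo–Rudy 1991 (LR91) ionic model.

## The problem

Electrical activation of heart tissue is commonly simulated with the
monodomain reaction–diffusion system

```
C_m ∂u/∂t − (1/β) ∇·(σ ∇u) − I_ionic(u, w) = I_stim(x, t)     in Ω
∂w/∂t = g(u, w),          n̂·(σ∇u) = 0 on ∂Ω
```

where `u` is the transmembrane potential (mV), `w` the m cell-state
variables (gates and [Ca²⁺]ᵢ for LR91, m = 7), `C_m` the membrane
capacitance (µF/cm²), `β` the surface-to-volume ratio (cm⁻¹) and `σ(x)`
the conductivity tensor built from the local fibre direction f as
`σ = σ_t I + (σ_l − σ_t) f fᵀ`.

Standard practice uses piecewise-linear elements (p = 1), which need very
fine meshes to get the conduction velocity (CV) of the steep activation
wavefront right.  This package raises the polynomial degree instead:

* **Hierarchical basis** for `u`, degrees p = 1…4 on intervals and
  triangles — the degree-p basis is a prefix of the degree-(p+1) basis, so
  the linear (vertex) block is a leading sub-block of every matrix.
* **Gauss–Lobatto nodal treatment** of `w` at degree p̃ (default 4,
  up to 6): the non-diffusing states reduce to independent ODE systems at
  the nodal points; taking p̃ ≥ p is what preserves the full O(h^{p+1})
  convergence of `u` (with p̃ = 1 every p ≥ 2 scheme is clipped to
  second order — reproduced in the test suite).
* **Matrix-based right-hand side**: the total current is interpolated on
  the nodal points, converted element-locally from nodal to hierarchical
  coefficients, and the load vector is a single sparse product with a
  rectangular "nested" mass matrix.  A direct quadrature assembler is kept
  as an independent oracle and the two agree to 1e-11.
* **Continuity-repaired LR91**: the published h/j gate rates switch
  between two analytic branches at −40 mV and are discontinuous there,
  which silently destroys high-order spatial convergence.
  `lr91_noble_form()` blends the branches with a logistic switch;
  `scan_rate_discontinuities()` finds such defects in any model.
* **Rule-based fibre fields**: fixed axis, bivariate-cubic angle fields,
  and Laplace–Dirichlet fields that steer fibres around holes (blood
  vessels) via a zero-flux harmonic potential.
* Semi-implicit backward Euler in time; CG with an ILU preconditioner
  built from the linear block only.

## Worked example

A 2 cm strand, stimulated at the left end, quartic elements:

```python
import numpy as np
from hpmono import (build_interval_mesh, lr91_noble_form,
                    PhysicalConstants, SolverConfig, run_simulation)
from hpmono.drivers import stimulus_1d
from hpmono.analysis import cv_1d

mesh = build_interval_mesh(6.0, 0.01)          # 6 cm, h = 0.01 cm
res = run_simulation(
    mesh, lr91_noble_form(), 1.0,              # sigma = 1 S/m
    stimulus_1d(),                             # 2 ms ramp to 80 uA/cm^2
    PhysicalConstants(C_m=1.0, beta=10962.0),  # beta calibrated, see below
    SolverConfig(p=4, p_tilde=4, dt=0.01, t_end=120.0))

x = mesh.vertices[:, 0]
t2 = res.activation[np.argmin(np.abs(x - 2.0))]
t4 = res.activation[np.argmin(np.abs(x - 4.0))]
print(f"activation at 2 cm: {t2:.2f} ms, at 4 cm: {t4:.2f} ms")
print(f"CV = {cv_1d(t2, t4):.2f} cm/s")
```

prints

```
activation at 2 cm: 32.14 ms, at 4 cm: 63.14 ms
CV = 64.52 cm/s
```

i.e. the wavefront passes the 2 cm and 4 cm probes 31 ms apart, a
conduction velocity of 64.5 cm/s — the physiological fast (along-fibre)
velocity the surface-to-volume ratio was calibrated to.  Dropping the
conductivity to 0.2 S/m (the transverse value) reproduces the √5-slower
velocity of 28.8 cm/s without retuning anything.

There is also a CLI (`hpmono cell run`, `hpmono mesh square`,
`hpmono run --config sim.toml`, `hpmono driver table1|table5|fig45`) for
shell use; `hpmono run` consumes a TOML config with `[mesh]`, `[physics]`,
`[stimulus]` and `[solver]` tables and writes activation CSVs and legacy
VTK snapshots.

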