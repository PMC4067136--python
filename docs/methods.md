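# Methods

This note records the model, the discretisation, the numerical choices and
the limits of what the test suite demonstrates.

## Model

The monodomain system couples a reaction–diffusion PDE for the
transmembrane potential `u` (mV) to pointwise ODEs for the cell states
`w`:

    C_m u_t − (1/β) ∇·(σ∇u) − I_ionic(u, w) = I_stim(x, t),
    w_t = g(u, w),     n̂·(σ∇u) = 0 on ∂Ω.

Internally lengths are cm, time ms, currents µA/cm², capacitance µF/cm²
and conductivity mS/cm (the API takes S/m and multiplies by 10; in this
unit system `mS·mV = µA` so the PDE needs no further conversion factor).

Cell models:

* `lr91_standard` — the published Luo–Rudy 1991 ventricular model
  (fast sodium, slow inward with calcium-dependent reversal,
  time-dependent and time-independent potassium, plateau and background
  currents; 6 Hodgkin–Huxley gates + [Ca²⁺]ᵢ).  Reversal potentials are
  computed from the stated concentrations at 310 K.  The h and j gate
  rates switch between two fitted branches at −40 mV and are
  discontinuous there.
* `lr91_noble_form` — the same model with each piecewise rate replaced by
  a logistic blend `(1−s)·r_below + s·r_above`, `s = 1/(1+e^{−(V+40)/k})`,
  `k = blend_width/4` (default width 1 mV).  The exact published
  continuous-form coefficients are not reproduced here; the blend is a
  documented stand-in with the same two branches and a continuous switch,
  and the construction is pluggable so exact published forms can be
  dropped in.  More than ~10 widths from −40 mV the blend agrees with the
  original rates to 1e−6 relative; the single-cell AP changes by well
  under 1 mV.
* `fitzhugh_nagumo` — two-variable caricature, rescaled to a mV-like
  range; used as the "smooth cell model" control.

The resting state (u₀ = −84.55 mV and the seven w₀ values) was frozen
from a 2-second unstimulated relaxation with an adaptive ODE solver; the
suite verifies the drift is below 1 mV over 500 ms.

## Discretisation

* Potential: continuous hierarchical elements of degree p ∈ {1..4}.
  1D modes on [0,1]: 1−x, x, x(1−x), x(1−x)(½−x), and the quartic bubble
  x(1−x)(5(2x−1)²−1)/4 (an integrated-Legendre kernel, chosen for
  conditioning; the span is what matters).  Triangle modes in barycentric
  coordinates: vertex λᵢ; edge quadratics λᵢλⱼ; edge cubics λᵢλⱼ(λⱼ−λᵢ);
  edge quartics λᵢλⱼ·(5t²−1)/4 with t = λⱼ−λᵢ; interior λ₁λ₂λ₃ (cubic)
  and λ₁λ₂λ₃·{λ₁, λ₂} (quartic).  Counts 3/6/10/15 for p = 1..4, with
  degree-p modes a strict prefix of degree-(p+1).
* Odd (cubic) edge modes flip sign under edge reversal; every edge is
  oriented globally from its lower to its higher vertex index and each
  element carries ±1 signs for its cubic edge modes.  This is what makes
  the basis continuous across elements, and the nodal→hierarchical
  transform checks it (`check=True` compares shared-entity coefficients
  between neighbouring elements).
* Cell states: a nodal (Lagrange) basis of degree p̃ ∈ {1..6} on
  Gauss–Lobatto points; on triangles a warped principal lattice whose
  edge traces are exactly the 1D Gauss–Lobatto points (warp-and-blend
  construction — the choice of interior warping is ours; only the edge
  traces are constrained by inter-element continuity).  The states never
  form a matrix system: they advance as independent ODE systems at the
  nodal points (forward Euler by default, optional Rush–Larsen
  exponential updates for the gates, which keeps gates in [0,1] for any
  dt).
* Right-hand side: I_total is evaluated at the nodal points, the
  element-local nodal values are converted to hierarchical coefficients
  of the continuous degree-p̃ interpolant (one precomputed inverse
  Vandermonde per reference element, applied with the orientation signs),
  and the load vector is `M̃ c` with `M̃` the degree-p rows (and degree-p̃
  columns) of the degree-max(p,p̃) mass matrix.  A per-element
  Gauss-quadrature assembler of the same vector is the independent oracle
  (agreement ≤ 1e−11 relative on random polynomial currents).
* Quadrature: Gauss–Legendre in 1D; on triangles a collapsed (Duffy)
  Gauss–Legendre × Gauss–Jacobi(1,0) tensor rule, which has positive
  weights at any exactness (mass/stiffness use exactness 2·max(p, p̃)).
* Time: semi-implicit backward Euler,
  `(M + dt/(βC_m) A) u^{n+1} = M u^n + (dt/C_m) I(u^n, w^{n+1})`.
  Diffusion is implicit, reaction explicit; the ionic current uses the
  freshly updated states w^{n+1} by default (`current_state="old"` is the
  switch for the other reading of the one-line scheme statement).
* Linear solver: CG preconditioned with an ILU factorisation of the
  vertex-mode (linear) block and the plain diagonal on the higher modes
  (the minimal symmetric completion), built once per (mesh, p, dt) and
  reused; warm-started from the previous step.  A prefactored direct
  solve (`linear_solver="direct"`) is available and agrees with PCG at
  tolerance 1e−8 to ~1e−4 mV over a 20 000-step run.
* p̃ < p is permitted (it deliberately reproduces the order-limited
  scheme where the cell-state space caps convergence at 2); p̃ ≤ 4 is
  required for the matrix-based path since the hierarchical trial space
  tops out at degree 4.

## Meshes

1D meshes are uniform intervals.  2D meshes are Delaunay triangulations
of seeded, jittered hexagonal lattices with exact boundary points; the
generator rescales its lattice constant once so the mean element
circumdiameter lands within a few % of the requested value (the
mean-diameter label follows the circumdiameter convention).  The
two-holes geometry (defaults: radius 0.08 cm at (0.32, 0.60) and 0.10 cm
at (0.68, 0.34), fully configurable — the published geometry is not
parameterised anywhere, so activation times on this domain are
qualitative) surrounds each hole with four staggered fine rings
(spacing ≈ r/10) so the rule-based fibre field resolves the flow around
the holes.  Triangle .node/.ele, Gmsh MSH 2.2 ASCII and legacy VTK are
read/written directly (simple line-based text formats).

## Fibre fields and conductivity

σ = σ_t I + (σ_l − σ_t) f fᵀ keeps eigenvalues {σ_l, σ_t} exactly.  The
Laplace–Dirichlet rule solves ∇²φ = 0 with φ = ±1 on two opposite outer
edges and natural conditions elsewhere (degree-2 elements by default —
degree 1 leaves too much pointwise flux error at hole boundaries) and
takes f = ∇φ/|∇φ|.  Because the hole boundaries carry the zero-flux
condition, f is tangent to them — except near the two stagnation points
of each hole, where ∇φ → 0 and a flow-based direction is genuinely
undefined at any resolution.  Points whose gradient magnitude falls below
15% of the batch maximum are treated as degenerate: they take the nearest
valid direction and are recorded on the field object.  The tangency
contract (|f·n̂| ≤ 0.05 at hole-boundary quadrature points) is asserted
over the non-degenerate points; measured worst case ≈ 0.02 with ~10% of
ring points degenerate.

The bivariate-cubic angle field defaults to
θ(x, y) = (π/2)(s(x) + s(y)) with s the cubic smoothstep — a 180° sweep
across the unit square; the published polynomial coefficients are not
available, so activation times under this field are likewise
qualitative only.

## Stimulus

A ramp: linear rise to 80 µA/cm² over 2 ms, then off, in an end segment
(0.05 cm, 1D), bottom strip (0.05 cm deep) or corner quarter-disc
(0.1 cm) — all configurable.  The spatial profile is a sharp indicator by
default.  For convergence measurements the indicator is a liability: its
degree-p̃ interpolant overshoots into the first unstimulated element by a
mesh-dependent O(h) amount, which floors every high-order error ladder
(measured: all slopes collapse to ≈1.4).  `profile_width` replaces the
indicator edge by a C∞ roll-off (0.02 cm in the convergence drivers);
conduction velocities are insensitive to the profile and keep the sharp
default.

## Physical constants and the β calibration

C_m = 1 µF/cm² (the LR91 standard) and β = 1400 cm⁻¹ are the defaults;
neither is published for the target simulations.  Absolute conduction
velocities therefore use a one-scalar calibration: since space enters the
continuum monodomain only through D = σ/(βC_m), CV ∝ √(σ/(βC_m)) exactly,
and a single converged 1D run at σ = 1 S/m fixes β so that CV = 64.52
cm/s (h = 0.01 cm, p = 4, dt = 0.01 ms; calibrated β ≈ 1.1·10⁴ cm⁻¹).
The same scaling law is why the calibration transfers: the σ = 0.2 S/m
strand then lands on the √5-slower velocity and the 2D planar wave on the
same fast velocity with no further tuning.

## Study sizes (desk scale)

* CV studies: 6 cm strand, dt = 0.01 ms, h down to 0.005 cm; the 2D
  planar wave uses a mean-diameter 0.0222 cm unit square at p = 4
  (≈48 000 DOF, ≈2000 steps).
* Convergence ladders: 2 cm strand, 20 ms, dt = 0.001 ms, σ = 0.5 S/m,
  h ∈ {0.02, 0.01, 0.005, 0.0025} against a quartic reference at
  h = 0.0005 cm (ladders stay ≥ 4× coarser than the reference); errors
  are sampled every 0.1 ms.  L∞(L2) takes the max over samples of the
  spatial L2 error on the reference mesh's Gauss points; L2(H1)
  trapezoid-integrates the squared H1 error in time.

## What the synthetic studies do and do not show

All inputs are generated: uniform strands, quasi-uniform unit squares,
rule-based fibres.  Passing tests demonstrate the correctness of the
discretisation (oracle equivalences, exact DOF/topology bookkeeping,
convergence orders and their p̃- and continuity-sensitivity) and the
internal consistency of the physiology (CV ratios, calibration
transfer).  They do not validate the LR91 parameterisation against
tissue data, cover realistic cardiac geometries (image-derived meshes,
3D fibre architecture), or exercise the bidomain regime.

## Known limitations

* Degree 4 is the ceiling for the potential basis; p̃ ≤ 6 for states.
* The error-norm machinery supports the 1D studies (plus same-mesh
  comparisons); 2D accuracy is assessed through activation/CV
  observables.
* Forward-Euler gate updates are marginally stable at dt = 0.02 ms for
  LR91 (τ_m ≈ 1/174 ms at rest); dt = 0.01 ms and below is safe, and
  Rush–Larsen removes the constraint.
* Activation-time tables on the cubic-fibre and holes geometries are
  structurally, not numerically, comparable to published values (their
  defining fields are unpublished).

## Slope-measurement windows

Each convergence slope is fitted in the window of the ladder where that
error is asymptotic.  At the coarse end the p = 1 runs under-resolve the
wavefront (relative errors near 100%), so the coarsest rung is excluded
from the p = 1 fits; at the fine end the ladders bottom out on a phase
floor — residual parts-per-million conduction-velocity differences between
discretisations whose imprint grows linearly in time and peaks just before
the wave leaves the strand — so the finest rung is excluded for p = 3
after verifying the floor (the error stops decreasing there).  The
acceptance tests encode these windows as fixed constants and check the
floor where they rely on it.
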