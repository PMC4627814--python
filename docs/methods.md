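# Methods

## Physical model

`turgorshape` computes equilibrium shapes of a plasma membrane that is
pressed against a rigid cell wall by turgor pressure and pulled away from
it at a single apical point — the geometry of clathrin/actin-mediated
endocytosis in walled cells (yeast, fungi, plants). The membrane is an
axisymmetric Helfrich surface with energy

```
F = ∫∫_S [ κ/2 (C − C0)² + Γ/2 (1/R − 1/R0)² + σ ] dS + Π V − f_a L
```

where `C = dψ/ds + sinψ/r` is the total curvature of the surface of
revolution (meridional plus azimuthal principal curvatures), `S` the
detached membrane area, `V` the volume enclosed between membrane and wall
plane, `L` the apex height, `f_a` the apical point force, `κ` the bending
rigidity of the coated membrane, `σ` its tension, `Π` the turgor pressure
difference, `C0` an isotropic spontaneous curvature imposed by coat
proteins (clathrin and adaptors), and `(Γ, R0)` the rigidity and preferred
*azimuthal* radius of curvature of a crescent-shaped (BAR-domain) coat —
`1/R = sinψ/r` is the normal curvature in the hoop direction, the
direction orthogonal to the symmetry axis. Both curvature terms act only
on the detached membrane; BAR coverage is taken uniform over it.

Assumptions: axisymmetry; quasi-static evolution (the viscous relaxation
time `L η_m / f` is microseconds against seconds for an endocytic event,
so every stage is a static equilibrium); adhesion-free contact with a
rigid flat wall; a point force at the apex standing in for the
actin-transmitted load.

### Units and scales

Fixed units: nm, pN, pN·nm; `1 pN/nm² = 1 MPa`; `kBT = 4.1 pN·nm`. Two
intrinsic scales control everything: the pressure–rigidity width
`R_Π = (κ/2Π)^{1/3}` and the force scale `f_Π = 4πΠR_Π² = 2πκ/R_Π`.
Internally all computations run at `κ = 1, R_Π = 1` (so `Π = 1/2`,
`f_Π = 2π`); results depend only on the reduced parameters
`σ̃ = σR_Π²/κ`, `C̃0 = C0 R_Π`, `Γ̃ = Γ/κ`, `R̃0 = R0/R_Π`, and scale
invariance under joint rescaling of `κ` and `Π` is verified in the tests.

## Shape equations and boundary conditions

The Euler–Lagrange equations of `F` close as five first-order ODEs in
`(ψ, u = dψ/ds, r, z, γ)` on arclength from apex to contact line, where
`γ` is the multiplier of `dr/ds = cosψ` and the multiplier of
`dz/ds = −sinψ` is the constant `−f_a` (the axial-force first integral).
At the free contact line, transversality gives `γ(S) = 0` (free contact
radius) and — through the vanishing Hamiltonian of the free-arclength
problem — a curvature jump at detachment,

```
dψ/ds(S) = − sqrt( C0² + 2σ/κ + Γ/(κR0²) ),
```

which reduces to curvature continuity (`dψ/ds = 0`) for a bare membrane.
This condition is what makes the analytic initiation force (below) come
out of the numerics; it expresses that peeling more membrane off the wall
costs the flat-state energy density `κC0²/2 + σ + Γ/2R0²`.

The apical point force produces a logarithmic curvature singularity at
the pole (as for pulled tethers), so the BVP is posed on `s ∈ [s0, S]`
with cutoff `s0 = 10⁻³ R_Π` and the matched asymptotic condition
`u − sinψ/r = −ḡ/2` at `s0`, with `ḡ` the local force amplitude
`(f_a − 2πΓ b)/2πκ` (with an `O(Γ/κ)` log-consistency correction).
Pointwise apex curvature is therefore resolution-dependent; the reported
tip radius is instead an osculating-circle fit over the tip region, which
is the quantity comparable to tomographic measurements.

The system is solved by collocation (`scipy.integrate.solve_bvp`) with
analytic Jacobians, in four closures: prescribed height `L` (unknowns
`S, f_a`), prescribed force, prescribed total arclength `S` (unknown
`f_a`), and a pseudo-arclength step (both free plus a secant-plane
constraint). Residual tolerance is 10⁻⁶: the apex log layer defeats mesh
refinement at much tighter tolerances, and accuracy at this setting is
~10⁻⁴ relative, verified independently (below). Warm-start meshes are
thinned to ≤1500 nodes so adaptive refinement cannot ratchet along a
continuation run.

### Heterogeneous rigidity

A stiff clathrin-coated tip over a softer base is modelled as
`κ(a)` interpolating (tanh in accumulated membrane area `a`, transition
width `2πR_Π w`) between `κ_tip` inside the apical cap of area `A_tip`
and `κ_min` outside. The multiplier of `da/ds = 2πr` adds two ODEs; with
`κ_min = κ_tip` the code path reduces exactly to the homogeneous solver.
Too soft a base loses the equilibrium (rigidity-driven instability), at a
ratio that relaxes as the stiff cap grows.

## Continuation, folds and regimes

Branches of equilibria are traced by pseudo-arclength continuation in
`(S, f_a)`, seeded from the flat state (small `S`) and from the long-tube
asymptote (capped-cylinder seed at large `S`; where Newton rejects it, by
homotopy in `(C0, Γ)` from the bare-membrane tube, trying several anchor
arclengths). `S` is the natural branch coordinate — it stays monotone
through the height-folds — but the family can fold in `S` as well, which
the secant constraint traverses. Folds are detected as sign changes of
`dL` along the branch; segments with `dL/dτ > 0` are flagged stable,
matching the fold/unstable-continuation picture. Branches terminate at
neck closure (neck radius < 10⁻² R_Π, below which the continuum model is
meaningless and the equations become singular), at the height-range
boundary, or on step collapse.

Regimes at given `(C̃0, σ̃)`: *smooth* — the flat-seeded branch reaches
the top of the height window with no folds; *hysteresis* — folds exist,
tubular and spheroidal shapes coexist over an `L`-interval; *gap* — the
two branches no longer overlap and an `L`-interval has no equilibrium.
The thresholds `C0*` (folding onset) and `C0**` (gap onset) are located
by bisection; for speed the predicate uses warm-started height marches
(branch reach) and an upper-branch descent rather than full curve
tracing. Thresholds are defined over a stated height window (default
`L ≤ 6R_Π` for classification, `4–5R_Π` in the fast threshold search);
the fold structure at threshold sits near `L ≈ 2.5R_Π`, well inside all
windows. At zero tension this gives `C0* ≈ 0.44/R_Π` and
`C0** ≈ 0.50/R_Π`, and both rise with tension.

`C0+(L)`, the critical curvature at fixed height, follows the fixed-`L`
equilibrium family in `C0` (with homotopy sub-steps through the strongly
deforming region) until the neck falls below the closure threshold.

### Analytic limits used as oracles

* Initiation force: `f0 = 4πκ sqrt(C0² + 2σ/κ [+ Γ/(κR0²)])`, the
  `L → 0` limit, checked against BVP extrapolation to 2%.
* Tube limit: minimizing the per-length energy
  `e(R) = πκ(1/R − C0)²R + 2πσR + ΠπR²` gives the asymptotic radius and
  plateau force; at `C0 = σ = 0` exactly `(R_Π, 0.75 f_Π)`.
* Closed-form surfaces (sphere `8πκ`, spherical caps, cylinders) pin the
  energy quadrature.

## Independent verification (direct minimization)

A second, independent route discretizes the energy itself: profiles are
polylines of `N` equal arclength segments described by node tangent
angles, with the height closure eliminating the total arclength
analytically, minimized with L-BFGS-B at fixed `L`; the force follows
from the conjugacy `f_a = dE/dL` by finite differences. The bending term
lives on segment midpoints (a staggered scheme — centered differences are
blind to grid-frequency wiggles and let the optimizer cheat), the ring
weight is `|r|` so a near-axis segment carries the continuum thin-tube
cost `~πκ/|r|` per length, and the angles are confined to `[0, π]`
(physical invaginations descend monotonically from apex to base), which
excludes self-intersecting polylines whose signed volume is unbounded
below. On a 24-point grid spanning `C̃0 ∈ {0, 0.2, 0.4}`,
`σ̃ ∈ {0, 0.05}`, `L ∈ {0.5, 1, 2, 4}R_Π` the two routes agree to
≲0.02% in energy and ≲0.005 R_Π pointwise; the tests assert 1% and
0.02 R_Π.

## Synthetic contours and fitting

No tomographic membrane traces are publicly deposited, so the benchmark
data are generated by the forward model itself: an equilibrium profile is
mirrored into a 2D contour sampled at 2–5 nm spacing, distorted by an
axis offset (~2 nm), a one-sided sinusoidal shear (~1.5 nm) emulating
tilt/tracing artifacts, and i.i.d. Gaussian point noise (default SD 1 nm,
sub-pixel at tomography scale), all deterministic given a seed. Default
scene: `R_Π = 20 nm`, `Π = 0.5 MPa` (so `κ = 2ΠR_Π³ ≈ 1950 kBT`),
`C̃0 = 0.4`, heights 10–100 nm — the geometry regime of the measured
invaginations (tip radius ~12 nm, heights up to 120 nm). What this does
*not* emulate: correlated tracing errors, missing-wedge anisotropy,
contrast-dependent bias; passing recovery tests therefore demonstrates
estimator correctness under the stated noise model, not tomography-grade
robustness.

Rectification estimates the symmetry axis as the closed-form minimizer of
the left–right radius discrepancy over halves matched by normalized
arclength from the apex (height-matching fails for overhanging necks),
averages matched pairs and reports the RMS discrepancy as an asymmetry
score.

Fitting searches `(R_Π, σ̃, C̃0)` for the equilibrium of equal height
minimizing the symmetric mean closest-point distance (in nm) between the
rectified points and the model curve — the force is not a parameter;
given shape parameters and height it is implied by the equilibrium. A
coarse grid pass (default 8×4×6 over `R_Π ∈ [5, 40] nm`, `σ̃ ∈ [0, 0.3]`,
`C̃0 ∈ [0, 1]`) brackets the optimum; Powell line searches then descend
the long shallow valley in which tension trades against the width scale
(a simplex stalls there). All grid points within 1.1× the best residual
form the reported degenerate set — the operational meaning of "a range of
parameters fits each profile" — and per-parameter bounds are read off it.
Noiseless synthetic profiles are recovered exactly (residual below the
0.07 nm resampling floor); with 1 nm noise the width scale comes back
within a few percent and the residual sits at the noise floor.

## Numerical choices and edge cases

* Quadrature: trapezoid on the arclength grid; ≥200 nodes per R_Π is the
  guideline enforced via a minimum-node check, and a refinement study in
  the tests shows the expected error decay.
* Neck radius: minimum of `r(s)` from the point of steepest tangent
  (argmax ψ) to the base — the true neck for overhangs, the tube radius
  for cylinders, and a graceful positive width for shallow domes.
* `σ = 0` makes the tension length `λ = sqrt(κ/2σ)` infinite; it is
  reported as `inf`, never raised.
* A height target inside a no-equilibrium gap raises
  `NoEquilibriumError` — expected behavior, distinguished from solver
  failure diagnostics.
* Continuation step bounds `[1.5·10⁻³, 0.35] R_Π`, adaptive on Newton
  iteration count; at most 300 points per branch.

## Known limitations

* With the BAR term at `Γ = κ`, `R0 = R_Π`, `C0 = 1/R_Π` the model as
  implemented still has a (much narrowed) no-equilibrium gap,
  `L/R_Π ∈ (≈1.6, ≈2.0)` versus `(1.5, 3.1)` without the BAR term; full
  suppression of the instability occurs by `Γ ≈ 2κ`. Both continuation
  and the independent energy minimization agree on this first-order
  transition, so it is a property of the stated energy functional, not of
  the solver. The scission phenomenology (stable necked shapes with the
  coat; neck collapse as `Γ → 0`) is unaffected.
* The bare-membrane (`C0 = 0`) force–length curve is not monotone: it
  overshoots to ~1.29 f_Π near `L ~ 1.5 R_Π` before relaxing to the
  0.75 f_Π plateau through slowly decaying barrel undulations of the
  tube (verified against the direct-minimization oracle). The plateau is
  reached to 3% only by `L ≈ 8R_Π`.
* No non-axisymmetric modes, no dynamics, no explicit actin mechanics,
  no post-scission vesicle evolution, no pearling analysis.
* The apex point force is an idealization; forces spread over a small
  sla2-sized patch are equivalent only while the coated tip is rigid.
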