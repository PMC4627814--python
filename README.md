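# turgorshape

Membrane mechanics of endocytosis in walled cells (yeast, fungi, plants),
where turgor pressure — not membrane tension — is the dominant force
opposing invagination.

During clathrin/actin-mediated endocytosis the plasma membrane must be
pulled away from the cell wall against a pressure difference of order
1 MPa. `turgorshape` models the membrane as an axisymmetric Helfrich
surface pressed onto a rigid wall and pulled at its apex by a point force
f_a, with energy

    F = ∫∫_S [ κ/2 (C − C0)² + Γ/2 (1/R − 1/R0)² + σ ] dS + Π V − f_a L

(κ bending rigidity of the coated membrane, σ tension, Π turgor, C0 an
isotropic spontaneous curvature from coat proteins such as clathrin,
(Γ, R0) the rigidity and preferred azimuthal curvature radius of
crescent-shaped BAR-domain proteins, C the total curvature, V the
enclosed volume, L the invagination height). Shapes are controlled by two
scales: the width R_Π = (κ/2Π)^(1/3) and the force f_Π = 4πΠR_Π² =
2πκ/R_Π, which for measured parameters is 1000–5000 pN — the force the
actin machinery must deliver.

The package provides:

* **Equilibrium shapes** — the Euler–Lagrange boundary-value problem
  solved by collocation with analytic Jacobians, at prescribed height,
  force, or detached arclength (`solve_shape`), including spatially
  varying rigidity for a stiff clathrin tip over a softer base
  (`solve_heterogeneous`).
* **Force–length curves** — pseudo-arclength continuation through folds,
  seeded from the flat state and the long-tube asymptote
  (`trace_branch`).
* **Instability analysis** — classification of the smooth / hysteresis /
  no-equilibrium-gap regimes induced by spontaneous curvature, the
  thresholds C0* and C0**, the critical curvature C0+(L) at fixed height,
  and the scission scenario in which removing the BAR coat (Γ → 0)
  collapses the neck (`classify_regime`, `find_thresholds`,
  `critical_curvature_at_length`, `scission_test`).
* **An independent oracle** — direct minimization of the discretized
  energy, used to verify the BVP solver to ~10⁻⁴ relative accuracy
  (`direct_minimization_oracle`).
* **Synthetic contours and fitting** — pseudo-tomography membrane traces
  with noise and asymmetry, rectification to axisymmetric profiles, and
  recovery of (R_Π, σ, C0) by shape fitting, with the force implied
  (`generate_contour`, `rectify_contour`, `fit_profile`, `fit_report`).

## Worked example

A 45 nm tall invagination at the tomography-fitted scales (R_Π = 20 nm,
Π = 0.5 MPa, C0 = 0.4/R_Π):

```python
from turgorshape import ModelParams, solve_shape

p = ModelParams.from_nd(C0_nd=0.4, sigma_nd=0.0, R_Pi=20.0, Pi=0.5)
sol = solve_shape(p, L=45.0)
```

prints (see `examples/02_shape_and_energies.py`):

```
parameters: kappa = 8000 pN nm (1951 kBT), Pi = 0.5 pN/nm^2, C0 = 0.0200 /nm
apical force: 1977 pN  (0.787 f_Pi, f_Pi = 2513 pN)
height 45.0 nm, tip radius 10.9 nm, neck radius 15.0 nm
membrane area 9246 nm^2, displaced volume 51227 nm^3
energy breakdown (pN nm): bending 101766, pressure 25614, tension 0, total deformation 127379
```

The ~2000 pN pulling force is set by pressure times the invagination
cross-section; the 10.9 nm tip radius matches the ~12 nm measured on
electron tomograms; and the width scale implies a coated-membrane
rigidity of ~2000 kBT — fifty times a bare bilayer.

Tracing the whole force–length curve (`examples/01_force_length_curve.py`)
shows the signature of coat curvature: the force peaks at L ≈ 1.1 R_Π and
the initiation force f₀ = 4πκC0 is ~62% of that peak, so the hardest part
of endocytosis is the start — a snap-through profile that explains why
invaginations rarely stall once begun. At higher curvature the curve
folds: short tubular and tall spheroidal shapes coexist (hysteresis,
C0* ≈ 0.44/R_Π at σ = 0), and beyond C0** ≈ 0.50/R_Π an interval of
heights has no equilibrium at all — the neck closes, which is how pulling
alone can prime the membrane for scission.

The `examples/` directory has one short script per capability:
force–length curves, single shapes, instability regimes, BAR-removal
scission, and the synthetic-contour fitting pipeline.

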