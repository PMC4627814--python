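"""End-to-end: generate a noisy pseudo-tomography contour and fit it.

A model invagination (R_Pi = 20 nm, C0 = 0.4/R_Pi) is rendered as a 2D
traced contour with 1 nm point noise and mild left-right asymmetry, then
rectified to an axisymmetric profile and fitted.  The recovered width
scale R_Pi translates into the coat rigidity via kappa = 2 Pi R_Pi^3.
"""

from turgorshape import (
    FitOptions,
    ModelParams,
    SolverOptions,
    SyntheticSpec,
    fit_profile,
    fit_report,
    generate_contour,
    rectify_contour,
)

truth = ModelParams.from_nd(C0_nd=0.4, sigma_nd=0.0, R_Pi=20.0, Pi=0.5)
spec = SyntheticSpec(params=truth, noise_sd=1.0, axis_offset=2.0,
                     skew=1.5, spacing=3.0, seed=42)
contour = generate_contour(spec, L=60.0)
print(f"generated contour: {len(contour.points)} points, "
      f"truth R_Pi = 20 nm, C0 = 0.4/R_Pi")

rect = rectify_contour(contour)
print(f"rectified: height {rect.L:.1f} nm, recovered axis at "
      f"x = {rect.axis_x:.2f} nm (true offset 2.0 nm), "
      f"asymmetry {rect.asymmetry:.2f} nm")
print("(the asymmetry score is inflated by the narrow neck, where arclength")
print(" matching of the two noisy halves is most sensitive)")

fit = fit_profile([rect], FitOptions(n_grid=(5, 1, 4), sigma_free=False,
                                     polish_maxfev=80,
                                     solver=SolverOptions(tol=1e-4)))
print(f"fit: R_Pi = {fit.best['R_Pi']:.1f} nm, C0 = {fit.best['C0_nd']:.2f}/R_Pi, "
      f"residual {fit.residual:.2f} nm (noise floor ~ the 1 nm jitter)")

rep = fit_report(fit, Pi=0.5)
print(f"implied rigidity at Pi = 0.5 MPa: kappa = {rep['kappa_kBT']:.0f} kBT; "
      f"coat radius of curvature 2/C0 = {rep['radius_of_curvature_nm']:.0f} nm")
print(f"apical force at this stage: {rep['f_a_pN'][0]:.0f} pN")
print("\nA single noisy replicate recovers the width scale to ~15%; the")
print("median over 20 seeded replicates lands within a few percent (the")
print("recovery benchmark in the test suite).")
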