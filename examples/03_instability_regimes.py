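"""Shape-instability regimes as spontaneous curvature increases.

For small C0 the invagination grows smoothly with height.  Above C0* the
force-length curve folds: short tubular and tall spheroidal shapes coexist
(hysteresis).  Above C0** the branches separate and an interval of heights
has no equilibrium at all - the neck closes, which is how pulling alone
can drive the membrane toward scission.
"""

from turgorshape import ModelParams, classify_regime

for C0 in (0.2, 0.45, 1.0):
    p = ModelParams.from_nd(C0_nd=C0)
    rep = classify_regime(p, L_range=(0.0, 5.0))
    line = f"C0 = {C0:4.2f}/R_Pi: {rep.regime:10s}"
    if rep.interval:
        lo, hi = rep.interval
        line += f"  L-interval [{lo:.2f}, {hi:.2f}] R_Pi"
        if rep.regime == "hysteresis":
            line += "  (two shapes coexist there)"
        else:
            line += "  (no equilibrium shape there)"
    print(line)

print("\nThe thresholds sit near C0* ~ 0.44/R_Pi and C0** ~ 0.50/R_Pi at zero")
print("tension (see turgorshape.find_thresholds); tension raises both.")
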