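"""Synthetic pseudo-tomography contours of endocytic invaginations.

Electron tomograms of endocytic sites yield hand-traced 2D membrane
contours: a polyline running from the wall plane on one side, over the
invagination, back to the wall on the other side, sampled every few nm,
with tracing noise and mild left–right asymmetry.  No such traces are
publicly deposited, so this module generates statistically comparable
contours from the forward model itself: an equilibrium profile is
mirrored into a 2D contour, skewed, offset and jittered.  Every step is
deterministic given the seed, and a truth table records the generating
parameters for recovery benchmarks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import ModelParams
from .solver import ShapeSolution, SolverOptions, solve_shape

__all__ = ["SyntheticSpec", "Contour2D", "generate_contour", "make_benchmark_suite"]


@dataclass
class Contour2D:
    """A traced 2D membrane contour in the tomographic section plane.

    ``points`` is an (n, 2) array of (x, y) coordinates in nm, ordered
    from one wall contact to the other; y = 0 is the wall plane.
    """

    points: np.ndarray
    pixel_size: float = 1.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if self.points.shape[0] < 10:
            raise ValueError("contour needs at least 10 points")

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"x_nm": self.x, "y_nm": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Contour2D":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(points=df[["x_nm", "y_nm"]].to_numpy())


@dataclass
class SyntheticSpec:
    """Generation recipe for a batch of synthetic contours.

    Defaults emulate the tomography geometry of yeast endocytic sites:
    invaginations up to ~120 nm tall with a width scale R_Pi ~ 20 nm
    (so kappa ~ 2 Pi R_Pi^3), traced at 2-5 nm spacing with ~1 nm point
    noise and nm-scale left–right asymmetry.
    """

    params: ModelParams = field(
        default_factory=lambda: ModelParams.from_nd(
            C0_nd=0.4, sigma_nd=0.0, R_Pi=20.0, Pi=0.5))
    heights: tuple[float, ...] = (10.0, 30.0, 60.0, 100.0)  # nm
    noise_sd: float = 1.0  # nm, isotropic Gaussian per point
    axis_offset: float = 2.0  # nm, lateral shift of the symmetry axis
    skew: float = 1.5  # nm, amplitude of a single sinusoidal shear mode
    spacing: float = 3.0  # nm along the contour
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.spacing <= 0:
            raise ValueError("noise_sd must be >= 0 and spacing > 0")


def _resample_polyline(pts: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(s[-1] / spacing) + 1, 10)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


def generate_contour(
    spec: SyntheticSpec,
    L: float,
    options: SolverOptions | None = None,
    solution: ShapeSolution | None = None,
) -> Contour2D:
    """One synthetic contour at height L (nm): mirror, distort, jitter.

    The model equilibrium at (spec.params, L) is mirrored about the
    symmetry axis, shifted by ``axis_offset``, sheared by a single
    sinusoidal mode of amplitude ``skew`` (nonzero on one side only, so
    left and right halves genuinely differ), resampled at ``spacing`` and
    jittered with isotropic Gaussian noise.  Deterministic given
    ``spec.seed`` and L.
    """
    sol = solution or solve_shape(spec.params, L=L, options=options)
    r, z = sol.profile.r, sol.profile.z
    # resample one half from the apex, then mirror, so the noiseless
    # contour is exactly left-right symmetric about the apex point
    right = _resample_polyline(np.column_stack([r, z]), spec.spacing)
    left = np.column_stack([-right[:, 0], right[:, 1]])[::-1]
    pts = np.vstack([left, right[1:]])
    # smooth shear: lateral displacement growing with height, one-sided bias
    if spec.skew:
        pts[:, 0] += spec.skew * np.sin(0.5 * math.pi * pts[:, 1] / max(L, 1e-9)) \
            * (0.5 + 0.5 * np.tanh(pts[:, 0] / max(sol.params.R_Pi, 1e-9)))
    pts[:, 0] += spec.axis_offset
    if spec.noise_sd > 0:
        rng = np.random.default_rng((spec.seed, int(round(L * 1000))))
        pts = pts + spec.noise_sd * rng.standard_normal(pts.shape)
    return Contour2D(points=pts, seed=spec.seed,
                     meta=dict(L=L, noise_sd=spec.noise_sd,
                               axis_offset=spec.axis_offset, skew=spec.skew,
                               spacing=spec.spacing,
                               R_Pi=sol.params.R_Pi,
                               C0_nd=sol.params.C0_nd,
                               sigma_nd=sol.params.sigma_nd))


def make_benchmark_suite(
    spec: SyntheticSpec | None = None,
    out_dir=None,
    include_necked: bool = True,
    options: SolverOptions | None = None,
) -> tuple[list[Contour2D], dict]:
    """Ladder of contours over invagination stages plus a truth table.

    Produces one contour per height in ``spec.heights`` with the default
    parameters, plus (optionally) a necked shape from the hysteresis
    regime (C0 = 0.45/R_Pi, upper branch) and a near-closure shape at
    elevated curvature.  If ``out_dir`` is given, writes contour CSVs and
    ``truth.json`` there.
    """
    spec = spec or SyntheticSpec()
    R = spec.params.R_Pi
    contours: list[Contour2D] = []
    truth: dict = {"seed": spec.seed, "cases": []}

    def add(name: str, params: ModelParams, L: float, warm=None):
        sub = SyntheticSpec(params=params, heights=(L,), noise_sd=spec.noise_sd,
                            axis_offset=spec.axis_offset, skew=spec.skew,
                            spacing=spec.spacing, seed=spec.seed)
        sol = solve_shape(params, L=L, options=options, warm_start=warm)
        c = generate_contour(sub, L, solution=sol)
        c.meta["name"] = name
        contours.append(c)
        truth["cases"].append(dict(
            name=name, L_nm=L, R_Pi_nm=params.R_Pi, C0_nd=params.C0_nd,
            sigma_nd=params.sigma_nd, Gamma_nd=params.Gamma_nd,
            fa_pN=sol.f_a, neck_nm=sol.observables.neck_radius,
            tip_radius_nm=sol.observables.tip_radius,
            noise_sd=spec.noise_sd, seed=spec.seed))
        return sol

    for L in spec.heights:
        add(f"stage_L{int(round(L))}", spec.params, L)

    if include_necked:
        # hysteresis-regime spheroid: reach the upper branch from the tube side
        p_neck = ModelParams.from_nd(C0_nd=0.45, sigma_nd=spec.params.sigma_nd,
                                     R_Pi=R, Pi=spec.params.Pi)
        warm = solve_shape(p_neck, S=8.0 * R, options=options)
        add("necked", p_neck, 3.6 * R, warm=warm)
        # near-closure: curvature just under the fixed-height closure
        # threshold C0+(2.8 R_Pi) ~ 0.49/R_Pi, reached by warming along C0
        warm = None
        for c0 in (0.3, 0.38, 0.43, 0.46):
            p_close = ModelParams.from_nd(C0_nd=c0, sigma_nd=spec.params.sigma_nd,
                                          R_Pi=R, Pi=spec.params.Pi)
            warm = solve_shape(p_close, L=2.8 * R, options=options,
                               warm_start=warm)
        add("near_closure", p_close, 2.8 * R, warm=warm)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in contours:
            c.to_csv(out / f"{c.meta['name']}.csv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return contours, truth
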