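"""Rectification of traced contours and model-parameter fitting.

A traced tomographic contour runs from the wall plane on one side of the
invagination to the other, with tracing noise and mild asymmetry.  Fitting
proceeds in two stages:

1. :func:`rectify_contour` estimates the symmetry axis, pairs the two
   halves (by height where the radius is single-valued, by normalized
   arclength across overhanging necks), and averages them into a clean
   axisymmetric (s, r, z) profile.
2. :func:`fit_profile` searches the reduced parameter space
   (R_Pi, sigma_nd, C0_nd) for the equilibrium shape of equal height that
   minimizes the symmetric mean closest-point distance to the rectified
   profile(s).  The apical force is not a free parameter: given the shape
   parameters and the height, the equilibrium fixes f_a.

The objective is typically shallow along directions that trade sigma
against C0 — a given profile is fitted by a *range* of parameters — so the
result carries the whole near-optimal (degenerate) set alongside the best
point, and per-parameter bounds derived from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .core import KBT, ModelParams, ShapeProfile
from .solver import NoEquilibriumError, ShapeSolution, SolverError, SolverOptions, solve_shape
from .synthetic import Contour2D

__all__ = ["RectifiedProfile", "FitResult", "FitOptions",
           "rectify_contour", "fit_profile", "fit_report"]


class RectificationError(ValueError):
    """Contour cannot be reduced to an axisymmetric profile."""


@dataclass
class RectifiedProfile:
    """Axisymmetric (z, r) samples from apex (z = L) to base (z = 0)."""

    z: np.ndarray
    r: np.ndarray
    axis_x: float
    asymmetry: float  # RMS left-right radius discrepancy [nm]
    L: float

    def points(self) -> np.ndarray:
        return np.column_stack([self.r, self.z])


def _split_halves(points: np.ndarray):
    """Split a contour at its apex (max y) into left and right halves."""
    y = points[:, 1]
    i_apex = int(np.argmax(y))
    if i_apex < 3 or i_apex > len(points) - 4:
        raise RectificationError("apex at the contour boundary; not an invagination trace")
    left = points[: i_apex + 1][::-1]  # apex -> base
    right = points[i_apex:]
    return left, right


def _resample_by_fraction(pts: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise RectificationError("degenerate contour half")
    f = s / s[-1]
    fi = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(fi, f, pts[:, 0]), np.interp(fi, f, pts[:, 1])])


def rectify_contour(contour: Contour2D, n_samples: int = 200) -> RectifiedProfile:
    """Straighten a 2D contour to an axisymmetric profile.

    The symmetry axis x0 minimizes the RMS difference between left radii
    (x0 - x_left) and right radii (x_right - x0) over halves matched by
    normalized arclength from the apex (which also handles overhanging
    necks, where radius is not single-valued in height); the closed-form
    minimizer is the mean midpoint of matched pairs.  Radii and heights of
    matched pairs are then averaged and the result resampled apex -> base.
    """
    pts = np.asarray(contour.points, float)
    left, right = _split_halves(pts)
    nL = max(n_samples, 30)
    lh = _resample_by_fraction(left, nL)
    rh = _resample_by_fraction(right, nL)
    # x0 minimizing sum((x0 - xl) - (xr - x0))^2 -> mean of (xl + xr)/2
    x0 = float(np.mean(0.5 * (lh[:, 0] + rh[:, 0])))
    r_left = x0 - lh[:, 0]
    r_right = rh[:, 0] - x0
    asym = float(np.sqrt(np.mean((r_left - r_right) ** 2)))
    r = 0.5 * (r_left + r_right)
    z = 0.5 * (lh[:, 1] + rh[:, 1])
    # anchor the base on the wall plane and the apex on the axis
    z = z - z[-1]
    r = np.maximum(r, 0.0)
    r[0] = 0.0
    if z[0] <= 0 or (z > 0).sum() < 10:
        raise RectificationError("contour does not rise above the wall plane")
    return RectifiedProfile(z=z, r=r, axis_x=x0, asymmetry=asym, L=float(z[0]))


@dataclass
class FitOptions:
    """Search configuration for :func:`fit_profile`.

    The default grid spans the physically expected ranges of the reduced
    parameters; a coarse grid pass brackets the optimum and a simplex
    refinement polishes it.  ``sigma_free=False`` pins sigma_nd to 0
    (the tension-negligible regime).
    """

    R_Pi_bounds: tuple[float, float] = (5.0, 40.0)
    sigma_bounds: tuple[float, float] = (0.0, 0.3)
    C0_bounds: tuple[float, float] = (0.0, 1.0)
    n_grid: tuple[int, int, int] = (8, 4, 6)  # R_Pi, sigma, C0
    sigma_free: bool = True
    degeneracy_factor: float = 1.1
    polish: bool = True
    polish_maxfev: int = 200
    solver: SolverOptions = field(default_factory=lambda: SolverOptions(tol=1e-5))


@dataclass
class FitResult:
    best: dict  # {"R_Pi", "sigma_nd", "C0_nd"} plus per-profile f_a
    residual: float  # mean symmetric point-to-curve distance [nm]
    degenerate_set: list  # [(params dict, residual), ...] within tolerance
    bounds: dict  # per-parameter (lo, hi) over the degenerate set
    n_evaluations: int = 0


def _profile_distance(obs_pts: np.ndarray, model: ShapeSolution) -> float:
    """Symmetric mean closest-point distance between profile point sets [nm]."""
    mod_pts = np.column_stack([model.profile.r, model.profile.z])
    # subsample the dense model curve for the reverse direction
    t1 = cKDTree(mod_pts)
    d1, _ = t1.query(obs_pts)
    t2 = cKDTree(obs_pts)
    step = max(1, mod_pts.shape[0] // 200)
    d2, _ = t2.query(mod_pts[::step])
    return 0.5 * (float(d1.mean()) + float(d2.mean()))


class _ModelCache:
    """Warm-started equilibrium solves binned by reduced parameters.

    Solutions are nondimensional up to the scale R_Pi, so the natural
    warm-start key is (sigma_nd, C0_nd) with the reduced height L/R_Pi;
    the stored solution closest in reduced height seeds the next solve.
    """

    def __init__(self, options: SolverOptions):
        self.options = options
        # (sigma_nd, C0_nd, L_nd, solution); nearest entry seeds the solve
        self.store: list[tuple[float, float, float, ShapeSolution]] = []
        self.failed: set[tuple[float, float, float]] = set()
        self.n_solves = 0

    def _nearest(self, sigma_nd, C0_nd, L_nd):
        if not self.store:
            return None
        def dist(e):
            return (4.0 * abs(e[0] - sigma_nd) + 2.0 * abs(e[1] - C0_nd)
                    + 0.5 * abs(e[2] - L_nd))
        return min(self.store, key=dist)[3]

    def solve(self, R_Pi: float, sigma_nd: float, C0_nd: float, L: float) -> ShapeSolution:
        L_nd = L / R_Pi
        # remember infeasible reduced heights: the optimizer revisits them
        fkey = (round(sigma_nd, 3), round(C0_nd, 3), round(L_nd, 1))
        if fkey in self.failed:
            raise NoEquilibriumError("cached infeasible parameter point")
        params = ModelParams.from_nd(C0_nd=C0_nd, sigma_nd=sigma_nd,
                                     R_Pi=R_Pi, Pi=0.5)
        warm = self._nearest(sigma_nd, C0_nd, L_nd)
        self.n_solves += 1
        try:
            sol = solve_shape(params, L=L, options=self.options,
                              warm_start=warm, fallback=False)
        except (NoEquilibriumError, SolverError):
            self.failed.add(fkey)
            raise
        self.store.append((sigma_nd, C0_nd, L_nd, sol))
        if len(self.store) > 40:
            del self.store[0]
        return sol


def fit_profile(
    profiles: list[RectifiedProfile],
    options: FitOptions | None = None,
) -> FitResult:
    """Fit (R_Pi, sigma_nd, C0_nd) to one or more rectified profiles.

    For each candidate parameter point the model equilibrium at each
    profile's height is solved (the force f_a is implied) and the mean
    symmetric closest-point distance accumulated.  Parameter points whose
    equilibrium does not exist at a required height (no-equilibrium gap)
    are excluded as infeasible rather than failing the fit.  Returns the
    best point, its per-profile forces, and the degenerate set of grid
    points within ``degeneracy_factor`` of the best residual.
    """
    if not profiles:
        raise ValueError("need at least one rectified profile")
    opts = options or FitOptions()
    cache = _ModelCache(opts.solver)
    obs = [p.points() for p in profiles]
    heights = [p.L for p in profiles]

    memo: dict[tuple[float, float, float], tuple[float, list | None]] = {}

    def objective(R_Pi, sigma_nd, C0_nd):
        if not (opts.R_Pi_bounds[0] <= R_Pi <= opts.R_Pi_bounds[1]):
            return math.inf, None
        if not (opts.sigma_bounds[0] <= sigma_nd <= opts.sigma_bounds[1]):
            return math.inf, None
        if not (opts.C0_bounds[0] <= C0_nd <= opts.C0_bounds[1]):
            return math.inf, None
        mkey = (round(R_Pi, 4), round(sigma_nd, 5), round(C0_nd, 5))
        if mkey in memo:
            return memo[mkey]
        total, fas = 0.0, []
        for pts, L in zip(obs, heights):
            try:
                sol = cache.solve(R_Pi, sigma_nd, C0_nd, L)
            except (NoEquilibriumError, SolverError):
                memo[mkey] = (math.inf, None)
                return math.inf, None
            total += _profile_distance(pts, sol)
            fas.append(sol.f_a)
        memo[mkey] = (total / len(obs), fas)
        return memo[mkey]

    nR, nS, nC = opts.n_grid
    R_grid = np.linspace(*opts.R_Pi_bounds, nR)
    S_grid = np.linspace(*opts.sigma_bounds, nS) if opts.sigma_free else np.array([0.0])
    C_grid = np.linspace(*opts.C0_bounds, nC)
    evals = []
    for C0_nd in C_grid:          # inner loops keep the warm cache coherent
        for sigma_nd in S_grid:
            for R_Pi in R_grid:
                res, fas = objective(R_Pi, sigma_nd, C0_nd)
                if math.isfinite(res):
                    evals.append(((float(R_Pi), float(sigma_nd), float(C0_nd)), res, fas))
    if not evals:
        raise NoEquilibriumError("no feasible parameter point on the search grid")
    evals.sort(key=lambda e: e[1])
    (bR, bS, bC), best_res, best_fas = evals[0]

    if opts.polish:
        def vec_obj(v):
            r, _ = objective(v[0], v[1] if opts.sigma_free else 0.0,
                             v[2] if opts.sigma_free else v[1])
            return r if math.isfinite(r) else 1e3

        # the objective has a long shallow valley trading R_Pi against
        # sigma; Powell line searches descend it far better than a simplex
        if opts.sigma_free:
            x0 = np.array([bR, bS, bC])
            pb = [opts.R_Pi_bounds, opts.sigma_bounds, opts.C0_bounds]
        else:
            x0 = np.array([bR, bC])
            pb = [opts.R_Pi_bounds, opts.C0_bounds]
        best_x, best_val = x0, best_res
        for _ in range(2):
            res = minimize(vec_obj, best_x, method="Powell", bounds=pb,
                           options={"xtol": 1e-3, "ftol": 1e-6,
                                    "maxfev": opts.polish_maxfev})
            if res.fun < best_val - 1e-12:
                best_x, best_val = np.asarray(res.x), float(res.fun)
            else:
                break
        if opts.sigma_free:
            rr, ss, cc = best_x
        else:
            rr, cc = best_x
            ss = 0.0
        pol_res, pol_fas = objective(float(rr), float(ss), float(cc))
        if math.isfinite(pol_res) and pol_res < best_res:
            (bR, bS, bC), best_res, best_fas = (float(rr), float(ss), float(cc)), pol_res, pol_fas

    cut = best_res * opts.degeneracy_factor
    degenerate = [dict(R_Pi=e[0][0], sigma_nd=e[0][1], C0_nd=e[0][2], residual=e[1])
                  for e in evals if e[1] <= cut]
    if not degenerate:
        degenerate = [dict(R_Pi=bR, sigma_nd=bS, C0_nd=bC, residual=best_res)]
    bounds = {}
    for k in ("R_Pi", "sigma_nd", "C0_nd"):
        vals = [d[k] for d in degenerate] + [dict(R_Pi=bR, sigma_nd=bS, C0_nd=bC)[k]]
        bounds[k] = (float(min(vals)), float(max(vals)))
    return FitResult(
        best=dict(R_Pi=bR, sigma_nd=bS, C0_nd=bC, f_a=best_fas),
        residual=float(best_res),
        degenerate_set=degenerate,
        bounds=bounds,
        n_evaluations=cache.n_solves,
    )


def fit_report(fit: FitResult, Pi: float = 1.0) -> dict:
    """Physical parameters implied by a fit at an assumed turgor pressure.

    ``Pi`` in pN/nm^2 (= MPa).  kappa = 2 Pi R_Pi^3 follows from the
    definition of the width scale; the preferred radius of curvature of
    the coat is 2/C0.  Degenerate-set ranges are propagated.
    """
    R = fit.best["R_Pi"]
    kappa = 2.0 * Pi * R**3
    C0 = fit.best["C0_nd"] / R
    out = dict(
        Pi_assumed=Pi,
        R_Pi_nm=R,
        kappa_pN_nm=kappa,
        kappa_kBT=kappa / KBT,
        sigma_pN_per_nm=fit.best["sigma_nd"] * kappa / R**2,
        C0_per_nm=C0,
        radius_of_curvature_nm=(2.0 / C0 if C0 > 0 else math.inf),
        f_Pi_pN=4.0 * math.pi * Pi * R**2,
        f_a_pN=fit.best.get("f_a"),
        residual_nm=fit.residual,
    )
    lo, hi = fit.bounds["R_Pi"]
    out["kappa_kBT_range"] = (2.0 * Pi * lo**3 / KBT, 2.0 * Pi * hi**3 / KBT)
    out["R_Pi_range_nm"] = (lo, hi)
    out["C0_nd_range"] = fit.bounds["C0_nd"]
    out["sigma_nd_range"] = fit.bounds["sigma_nd"]
    return out
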