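"""Shape-instability analysis of curved, pressurized invaginations.

Isotropic spontaneous curvature C0 reshapes the force–length landscape.
With increasing C0 (at fixed tension) three regimes appear:

* ``smooth``      -- a single connected branch of equilibria; the shape
                     evolves continuously with the height L.
* ``hysteresis``  -- above a threshold C0*, tubular and spheroidal
                     branches coexist over an interval of L (folds in the
                     force–length curve, with an unstable segment between).
* ``gap``         -- above a second threshold C0**, the branches cease to
                     overlap: an interval of heights has no equilibrium at
                     all, and the neck closes (radius -> 0) at the branch
                     ends.

Anisotropic (BAR-domain) curvature with rigidity Gamma opposes the
instability: at C0 = 1/R_Pi the no-equilibrium gap shrinks sharply as
Gamma grows (from ~1.6 R_Pi wide at Gamma = 0 to ~0.4 R_Pi at
Gamma = kappa) and closes entirely near Gamma ~ 2 kappa, while removing
the coat (Gamma -> 0) at fixed height collapses the neck — a scission
trigger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .core import ModelParams
from .solver import (
    ForceLengthCurve,
    NoEquilibriumError,
    ShapeSolution,
    SolverError,
    SolverOptions,
    solve_shape,
    trace_branch,
)

__all__ = [
    "StabilityReport",
    "classify_regime",
    "find_thresholds",
    "critical_curvature_at_length",
    "energy_crossing",
    "branch_energy_components",
    "scission_test",
    "NECK_CLOSURE_EPS",
]

# neck radii below this fraction of R_Pi count as closed (continuum model
# is invalid below, and the shape equations become singular)
NECK_CLOSURE_EPS = 1e-2


@dataclass
class StabilityReport:
    regime: str  # "smooth" | "hysteresis" | "gap"
    C0: float  # spontaneous curvature at which classified [1/nm]
    sigma: float  # tension [pN/nm]
    interval: tuple[float, float] | None  # overlap (hysteresis) or gap L-range [nm]
    curve: ForceLengthCurve | None = None
    partial: bool = False  # continuation trouble: classification incomplete


def classify_regime(
    params: ModelParams,
    L_range: tuple[float, float] | None = None,
    options: SolverOptions | None = None,
    dS0: float = 0.15,
    max_points: int = 300,
) -> StabilityReport:
    """Classify the instability regime from traced branch topology.

    smooth: the flat-seeded branch reaches the top of the L-range with no
    folds.  hysteresis: folds are present (two branches coexist over the
    fold interval).  gap: the lower and upper branches terminate (neck
    closure) leaving an uncovered interval of heights.
    """
    R = params.R_Pi
    if L_range is None:
        L_range = (0.0, 6.0 * R)
    curve = trace_branch(params, L_range=L_range, options=options, dS0=dS0,
                         max_points=max_points)
    branches = [b for b in curve.branches if b.L.size]
    folds = curve.fold_points
    lower = branches[0]
    covered = float(max(b.L.max() for b in branches)) >= L_range[1] * 0.97

    if len(branches) >= 2:
        lowmax = float(lower.L.max())
        upmin = float(min(b.L.min() for b in branches[1:]))
        if upmin > lowmax + 1e-9:
            return StabilityReport(regime="gap", C0=params.C0, sigma=params.sigma,
                                   interval=(lowmax, upmin), curve=curve,
                                   partial=not covered)
        return StabilityReport(regime="hysteresis", C0=params.C0,
                               sigma=params.sigma,
                               interval=(upmin, lowmax), curve=curve,
                               partial=not covered)
    if folds:
        Ls = np.array([f[0] for f in folds])
        return StabilityReport(regime="hysteresis", C0=params.C0,
                               sigma=params.sigma,
                               interval=(float(Ls.min()), float(Ls.max())),
                               curve=curve, partial=not covered)
    if lower.termination == "neck_closure" and not covered:
        # branch ends in closure and no upper branch was reachable: the
        # remaining heights have no (numerically resolvable) equilibrium
        return StabilityReport(regime="gap", C0=params.C0, sigma=params.sigma,
                               interval=(float(lower.L.max()), float(L_range[1])),
                               curve=curve, partial=True)
    if not covered:
        return StabilityReport(regime="gap", C0=params.C0, sigma=params.sigma,
                               interval=(float(lower.L.max()), float(L_range[1])),
                               curve=curve, partial=True)
    return StabilityReport(regime="smooth", C0=params.C0, sigma=params.sigma,
                           interval=None, curve=curve, partial=not covered)


def _lower_branch_reach(C0_nd: float, sigma_nd: float, Gamma_nd: float,
                        R0_nd: float, L_max_nd: float,
                        opts: SolverOptions) -> float:
    """Largest height reachable on the flat-seeded branch (units R_Pi).

    Marches L upward with warm-started height solves; the march stalls at
    the first fold of the branch.  Below the instability threshold it
    reaches L_max_nd.
    """
    p = ModelParams.from_nd(C0_nd=C0_nd, sigma_nd=sigma_nd,
                            Gamma_nd=Gamma_nd, R0_nd=R0_nd)
    R = p.R_Pi
    # probes beyond a fold diverge; a tight mesh cap makes them fail fast
    probe_opts = dc_replace(opts, max_nodes=6000)
    warm = None
    L, dL, last = 0.35, 0.35, 0.0
    while L < L_max_nd + 1e-9:
        try:
            if warm is None:
                sol = solve_shape(p, L=L * R, options=opts, fallback=False)
            else:
                sol = solve_shape(p, L=L * R, options=probe_opts,
                                  warm_start=warm, fallback=False)
        except Exception:
            if dL < 0.04:
                return last
            L = last + 0.4 * dL
            dL *= 0.4
            continue
        warm, last = sol, L
        dL = min(dL * 1.3, 0.5)
        L = min(L + dL, L_max_nd)
        if last >= L_max_nd - 1e-9:
            break
    return last


def _upper_branch_min(C0_nd: float, sigma_nd: float, Gamma_nd: float,
                      R0_nd: float, L_max_nd: float,
                      opts: SolverOptions) -> float | None:
    """Smallest height reachable on the tube-seeded branch (units R_Pi)."""
    from .solver import _NDParams, _continue_branch, _tube_start

    p = ModelParams.from_nd(C0_nd=C0_nd, sigma_nd=sigma_nd,
                            Gamma_nd=Gamma_nd, R0_nd=R0_nd)
    nd = _NDParams.from_params(p)
    start, S_anchor = _tube_start(nd, L_max_nd + 3.0, opts)
    if start is None or not start.success:
        return None
    b = _continue_branch(nd, p, opts, S_start=S_anchor, direction=-1.0,
                         seed_kind=(start, S_anchor), L_max_nd=L_max_nd,
                         branch_id=1, dtau0=0.25, dtau_max=0.5, max_points=120)
    if not b.L.size:
        return None
    return float(b.L.min() / p.R_Pi)


def find_thresholds(
    sigma_nd: float = 0.0,
    Gamma_nd: float = 0.0,
    R0_nd: float = 1.0,
    C0_max_nd: float = 1.5,
    C0_min_nd: float = 0.05,
    tol_nd: float = 1e-2,
    L_max_nd: float = 6.0,
    options: SolverOptions | None = None,
) -> tuple[float | None, float | None]:
    """Bisect for the instability thresholds C0* and C0** (units 1/R_Pi).

    C0* is the onset of branch folding (smooth -> hysteresis): located as
    the smallest C0 at which the flat-seeded branch no longer reaches the
    top of the height range by warm-started continuation.  C0** is the
    onset of the no-equilibrium gap (hysteresis -> gap): the smallest C0
    at which the tube-seeded branch no longer reaches down to the fold of
    the flat-seeded branch.  Returns ``None`` for a threshold not
    bracketed in (0, C0_max_nd] (e.g. with a strong stabilizing BAR coat
    there is no instability at all).
    """
    opts = options or SolverOptions()
    reach_cache: dict[float, float] = {}

    def reach_at(c: float) -> float:
        if c not in reach_cache:
            reach_cache[c] = _lower_branch_reach(c, sigma_nd, Gamma_nd, R0_nd,
                                                 L_max_nd, opts)
        return reach_cache[c]

    def unstable(c: float) -> bool:
        return reach_at(c) < L_max_nd - 1e-6

    def has_gap(c: float) -> bool:
        reach = reach_at(c)
        if reach >= L_max_nd - 1e-6:
            return False
        upmin = _upper_branch_min(c, sigma_nd, Gamma_nd, R0_nd, L_max_nd, opts)
        if upmin is None:
            return True  # no reachable upper branch at all
        return upmin > reach + 1e-3

    if not unstable(C0_max_nd):
        return None, None
    lo, hi = C0_min_nd, C0_max_nd
    if unstable(lo):
        C0_star = lo
    else:
        a, b = lo, hi
        while b - a > tol_nd:
            m = 0.5 * (a + b)
            if unstable(m):
                b = m
            else:
                a = m
        C0_star = 0.5 * (a + b)

    if not has_gap(C0_max_nd):
        return C0_star, None
    a, b = C0_star, C0_max_nd
    while b - a > tol_nd:
        m = 0.5 * (a + b)
        if has_gap(m):
            b = m
        else:
            a = m
    return C0_star, 0.5 * (a + b)


def critical_curvature_at_length(
    L_nd: float,
    sigma_nd: float = 0.0,
    C0_max_nd: float = 1.6,
    tol_nd: float = 1e-2,
    options: SolverOptions | None = None,
) -> float:
    """Critical curvature C0+(L): neck closure at fixed height (units 1/R_Pi).

    Smallest C0 at which the equilibrium at height L has a neck radius
    below NECK_CLOSURE_EPS * R_Pi, or ceases to exist.  Found by bisection
    on C0 with warm-started height solves.
    """
    if L_nd <= 0:
        raise ValueError("L must be > 0")
    opts = options or SolverOptions()

    warm: ShapeSolution | None = None
    warm_c0 = 0.0

    def solve_at(c0: float):
        """Follow the fixed-height equilibrium family in C0.

        The shape deforms strongly across the near-instability region, so
        a failed warm step is retried through intermediate C0 sub-steps
        before the equilibrium is declared lost.
        """
        nonlocal warm, warm_c0
        p = ModelParams.from_nd(C0_nd=c0, sigma_nd=sigma_nd)
        try:
            sol = solve_shape(p, L=L_nd * p.R_Pi, options=opts,
                              warm_start=warm, fallback=warm is None)
        except (NoEquilibriumError, SolverError):
            if warm is None:
                raise
            for c_mid in np.linspace(warm_c0, c0, 8)[1:]:
                p_mid = ModelParams.from_nd(C0_nd=float(c_mid), sigma_nd=sigma_nd)
                try:
                    sol = solve_shape(p_mid, L=L_nd * p_mid.R_Pi, options=opts,
                                      warm_start=warm, fallback=False)
                except (NoEquilibriumError, SolverError):
                    return None
                warm, warm_c0 = sol, float(c_mid)
            return sol
        warm, warm_c0 = sol, c0
        return sol

    def neck_open(c0) -> bool:
        sol = solve_at(c0)
        if sol is None:
            return False
        return sol.observables.neck_radius / sol.params.R_Pi > NECK_CLOSURE_EPS

    a = 0.0
    if not neck_open(a):
        raise RuntimeError("neck closed already at C0 = 0; no threshold")
    # march up to bracket (warm starts keep this on the connected branch)
    b = None
    for c in np.linspace(0.1, C0_max_nd, 16):
        if neck_open(c):
            a = c
        else:
            b = c
            break
    if b is None:
        raise RuntimeError(f"no neck closure found up to C0 = {C0_max_nd}/R_Pi")
    while b - a > tol_nd:
        m = 0.5 * (a + b)
        if neck_open(m):
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def energy_crossing(params: ModelParams, L_range: tuple[float, float] | None = None,
                    options: SolverOptions | None = None,
                    report: StabilityReport | None = None):
    """Branch-preference table over the hysteresis overlap.

    Returns a DataFrame with per-L energies of the tubular and spheroidal
    branches over their overlap, the energy components, and the crossing
    height where the spheroidal branch becomes energetically preferred.
    Raises if the parameters are not in the hysteresis regime.  Passing a
    precomputed ``report`` from :func:`classify_regime` skips the tracing.
    """
    import pandas as pd

    rep = report or classify_regime(params, L_range=L_range, options=options)
    if rep.regime != "hysteresis":
        raise ValueError(f"energy_crossing needs the hysteresis regime, got {rep.regime!r}")
    curve = rep.curve
    R = params.R_Pi
    # split points into tubular (lower S) and spheroidal (upper S) sides of
    # the fold structure, using the L-folds of the connected curve
    pts = []
    for b in curve.branches:
        for j in range(b.L.size):
            pts.append((b.S[j], b.L[j], b.f_a[j], b.E_deform[j], b.neck_radius[j]))
    pts.sort()
    S = np.array([p[0] for p in pts])
    L = np.array([p[1] for p in pts])
    dL = np.diff(L)
    sign_changes = np.where(dL[:-1] * dL[1:] < 0)[0] + 1
    if sign_changes.size == 0:
        raise ValueError("no folds found; not a hysteresis curve")
    i_first, i_last = sign_changes[0], sign_changes[-1]
    lo, hi = rep.interval
    grid = np.linspace(lo, hi, 25)[1:-1]

    def interp_branch(idx):
        Lb = L[idx]
        order = np.argsort(Lb)
        out = {}
        for k, name in ((2, "f_a"), (3, "E_deform"), (4, "neck")):
            arr = np.array([pts[i][k] for i in idx])[order]
            out[name] = np.interp(grid, Lb[order], arr)
        return out

    tub = interp_branch(np.arange(0, i_first + 1))
    sph = interp_branch(np.arange(i_last, len(pts)))
    df = pd.DataFrame({
        "L_nm": grid,
        "E_tubular": tub["E_deform"],
        "E_spheroidal": sph["E_deform"],
        "fa_tubular": tub["f_a"],
        "fa_spheroidal": sph["f_a"],
        "preferred": np.where(sph["E_deform"] <= tub["E_deform"],
                              "spheroidal", "tubular"),
    })
    # per-branch energy components at the crossing need explicit solves
    dE = sph["E_deform"] - tub["E_deform"]
    if np.all(dE > 0):
        L_cross = float(grid[-1])
    elif np.all(dE < 0):
        L_cross = float(grid[0])
    else:
        L_cross = float(np.interp(0.0, dE[::-1], grid[::-1]))
    df.attrs["L_cross_nm"] = L_cross
    df.attrs["regime_interval_nm"] = rep.interval
    return df


def branch_energy_components(params: ModelParams, L: float,
                             options: SolverOptions | None = None,
                             curve: ForceLengthCurve | None = None):
    """Energy breakdown of both coexisting branches at one height.

    Returns (tubular, spheroidal) ShapeSolutions obtained by walking the
    branch from the flat and the tube side respectively.  A precomputed
    force-length ``curve`` skips the tracing.
    """
    opts = options or SolverOptions()
    R = params.R_Pi
    if curve is None:
        curve = trace_branch(params, L_range=(0.0, max(6.0 * R, 1.4 * L)),
                             options=opts)
    pts = []
    for b in curve.branches:
        for j in range(b.S.size):
            pts.append((b.S[j], b.L[j]))
    pts.sort()
    S = np.array([p[0] for p in pts])
    Lv = np.array([p[1] for p in pts])
    # crossings of the requested height along the S-ordered family
    cross = np.where((Lv[:-1] - L) * (Lv[1:] - L) <= 0)[0]
    if cross.size < 2:
        raise ValueError("height is not in the multi-branch overlap")
    i_lo, i_hi = cross[0], cross[-1]

    # tubular side: warm height march from a short invagination
    warm = None
    for L_step in np.linspace(0.4 * R, L, 6):
        warm = solve_shape(params, L=float(L_step), options=opts,
                           warm_start=warm)
    tub = warm

    # spheroidal side: pseudo-arclength descent along the upper branch
    # from the tube anchor (fold-safe), then a height solve at L from the
    # nearest upper-branch point
    from .solver import _NDParams, _package, _solve_nd, _tube_start

    nd = _NDParams.from_params(params)
    start, S_anchor = _tube_start(nd, max(L / R + 3.0, 6.0), opts)
    if start is None:
        raise SolverError("could not seed the spheroidal branch")
    S_cur, fa_cur = S_anchor, float(start.p[0])
    guess = (start.x, start.y, None)
    tS, tfa, dtau = -1.0, 0.0, 0.2
    sol = start
    for _ in range(200):
        L_cur = float(sol.y[3][0])
        if L_cur <= L / R + 0.05:
            break
        step = _solve_nd(nd, "pseudo",
                         guess=(guess[0], guess[1],
                                [S_cur + tS * dtau, fa_cur + tfa * dtau]),
                         opts=opts,
                         pseudo=(S_cur, fa_cur, tS, 0.5 * tfa, dtau))
        if not step.success:
            if dtau < 2e-3:
                raise SolverError("lost the spheroidal branch during descent")
            dtau *= 0.4
            continue
        S_new, fa_new = float(step.p[0]), float(step.p[1])
        nrm = math.hypot(S_new - S_cur, 0.5 * (fa_new - fa_cur))
        if nrm > 0:
            tS, tfa = (S_new - S_cur) / nrm, (fa_new - fa_cur) / nrm
        S_cur, fa_cur, sol = S_new, fa_new, step
        guess = (step.x, step.y, None)
        dtau = min(dtau * 1.3, 0.3)
    mode = "pseudo" if sol is not start else "arclength"
    warm_sph = _package(sol, nd, params, mode, fa_cur, S_cur, opts)
    sph = solve_shape(params, L=L, options=opts, warm_start=warm_sph,
                      fallback=False)
    return tub, sph


def scission_test(
    params: ModelParams,
    L: float,
    n_steps: int = 12,
    options: SolverOptions | None = None,
):
    """Neck radius vs Gamma as the BAR coat is removed at fixed height.

    Starting from a converged BAR-stabilized shape (Gamma = params.Gamma),
    Gamma is stepped toward 0 at fixed L.  Scission is declared when the
    neck radius falls below NECK_CLOSURE_EPS * R_Pi or the equilibrium is
    lost.  Returns a dict with the (Gamma, neck) table and the verdict.
    """
    opts = options or SolverOptions()
    R = params.R_Pi
    gammas = np.concatenate([np.linspace(params.Gamma, 0.05 * params.Gamma, n_steps),
                             [0.02 * params.Gamma, 0.01 * params.Gamma, 0.0]])
    rows = []
    warm = None
    scission = False
    for g in gammas:
        p = dc_replace(params, Gamma=float(g))
        try:
            sol = solve_shape(p, L=L, options=opts, warm_start=warm)
        except (NoEquilibriumError, Exception) as e:
            if not isinstance(e, NoEquilibriumError) and warm is None:
                raise
            rows.append((float(g), math.nan))
            scission = True
            break
        warm = sol
        neck = sol.observables.neck_radius
        rows.append((float(g), neck))
        if neck < NECK_CLOSURE_EPS * R:
            scission = True
            break
    return {
        "gamma_neck": rows,
        "scission": scission,
        "L": L,
        "eps_nm": NECK_CLOSURE_EPS * R,
    }
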