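"""Equilibrium shapes of a pressurized membrane pulled by an apical force.

The shape equations are the Euler–Lagrange equations of the energy

    F = ∫ 2πr [ κ/2 (ψ' + sinψ/r − C0)² + Γ/2 (sinψ/r − 1/R0)² + σ ] ds
        + Π ∫ π r² sinψ ds − f_a L ,

over axisymmetric profiles parameterized by arclength s from the apex
(r = 0, z = L) to the contact line with the wall (z = 0, ψ = 0).  With
multipliers γ(s), η(s) enforcing r' = cosψ and z' = −sinψ, η is constant
and equals −f_a (the axial force first integral), and the system closes as
five first-order ODEs in (ψ, u = ψ', r, z, γ).  Transversality at the free
contact line gives γ(S) = 0 (free contact radius) and, through the zero
Hamiltonian of the free-endpoint problem,

    ψ'(S) = −sqrt(C0² + 2σ/κ + Γ/(κ R0²)),

a curvature jump at detachment that reduces to ψ'(S) = 0 for a bare
membrane and reproduces the analytic initiation force
f0 = 4πκ sqrt(C0² + 2σ/κ) in the flat limit.

The apical point force makes the meridional curvature diverge
logarithmically at the apex (as for pulled tethers), so the BVP is posed
on s ∈ [s0, S] with a small cutoff s0 and an asymptotic matching condition
u − sinψ/r = −g/2 at s0, where g is the local force amplitude
(f_a − 2πΓ b)/(2πκ).

Everything internal is nondimensional: κ = 1, R_Π = 1 (hence Π = 1/2 and
f_Π = 2π).  Equilibrium families are traced by pseudo-arclength
continuation in (S, f_a), where S is the total detached arclength — the
natural branch coordinate, monotone through the folds of the force–length
curve (though the family can fold in S as well, which the secant-plane
step traverses).  Height-folds are detected a posteriori as sign changes
of dL along the branch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_bvp

from .core import (
    EnergyBreakdown,
    GeometricObservables,
    ModelParams,
    ShapeProfile,
    evaluate_energy,
    geometric_observables,
    initiation_force,
    tube_limit,
)

TWO_PI = 2.0 * math.pi
PI_ND = 0.5  # nondimensional turgor pressure (kappa = R_Pi = 1)

__all__ = [
    "SolverOptions",
    "ShapeSolution",
    "RigidityProfile",
    "ForceLengthCurve",
    "Branch",
    "SolverError",
    "NoEquilibriumError",
    "solve_shape",
    "solve_heterogeneous",
    "trace_branch",
]


class SolverError(RuntimeError):
    """BVP solver failed to converge."""


class NoEquilibriumError(SolverError):
    """No equilibrium shape exists (or could be found) for the requested target.

    Expected in the gap regime C0 > C0**, where an interval of heights has
    no static membrane shape.
    """


@dataclass(frozen=True)
class SolverOptions:
    """Numerical knobs of the boundary-value solver.

    s0 : apex arclength cutoff (units of R_Pi).
    tol : residual tolerance of the collocation solver.  The default
        10^-6 is set by the logarithmic curvature layer at the apex point
        force, which defeats mesh refinement at much tighter tolerances;
        solution accuracy at this setting is ~10^-4 (validated against
        direct energy minimization at the 10^-4 relative level).
    max_nodes : mesh-size cap of the collocation solver.
    n_mesh : number of initial mesh nodes for cold starts.
    guess_max_nodes : warm-start meshes are thinned to this size, so the
        adaptive mesh cannot ratchet up along a continuation run.
    """

    s0: float = 1e-3
    tol: float = 1e-6
    max_nodes: int = 30000
    n_mesh: int = 81
    guess_max_nodes: int = 1500


# ---------------------------------------------------------------------------
# nondimensional parameter bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _NDParams:
    C0: float
    sigma: float
    Gamma: float
    R0inv: float

    @classmethod
    def from_params(cls, p: ModelParams) -> "_NDParams":
        return cls(
            C0=p.C0_nd,
            sigma=p.sigma_nd,
            Gamma=p.Gamma_nd,
            R0inv=(1.0 / p.R0_nd) if p.Gamma > 0 else 0.0,
        )

    @property
    def base_slope(self) -> float:
        """|dψ/ds| at the contact line from the zero-Hamiltonian condition."""
        return math.sqrt(self.C0**2 + 2.0 * self.sigma + self.Gamma * self.R0inv**2)


def _rhs_factory(nd: _NDParams):
    C0, sig, Gam, R0i = nd.C0, nd.sigma, nd.Gamma, nd.R0inv

    def rhs(y: np.ndarray, fa: float) -> np.ndarray:
        psi, u, r, z, gam = y
        sn, cs = np.sin(psi), np.cos(psi)
        cphi = sn / r
        h = u + cphi - C0
        b = cphi - R0i
        hp = (TWO_PI * Gam * cs * b + PI_ND * math.pi * r**2 * cs
              + gam * sn - fa * cs) / (TWO_PI * r)
        up = hp - u * cs / r + sn * cs / r**2
        gamp = (TWO_PI * (0.5 * h**2 + 0.5 * Gam * b**2 + sig)
                - TWO_PI * cphi * (h + Gam * b)
                + 2.0 * PI_ND * math.pi * r * sn)
        return np.vstack([u, up, cs, -sn, gamp])

    def jac(y: np.ndarray, fa: float):
        """Analytic d(rhs)/dy (5,5,m) and d(rhs)/dfa (5,m)."""
        psi, u, r, z, gam = y
        m = psi.shape[0]
        sn, cs = np.sin(psi), np.cos(psi)
        cphi = sn / r
        h = u + cphi - C0
        b = cphi - R0i
        hp = (TWO_PI * Gam * cs * b + PI_ND * math.pi * r**2 * cs
              + gam * sn - fa * cs) / (TWO_PI * r)
        J = np.zeros((5, 5, m))
        # f1 = u
        J[0, 1] = 1.0
        # f2 = hp + g2, g2 = -u cs/r + sn cs/r^2
        dhp_dpsi = (-TWO_PI * Gam * sn * b + TWO_PI * Gam * cs * cs / r
                    - PI_ND * math.pi * r**2 * sn + gam * cs + fa * sn) / (TWO_PI * r)
        dhp_dr = (TWO_PI * Gam * cs * (-sn / r**2) + 2.0 * PI_ND * math.pi * r * cs) \
            / (TWO_PI * r) - hp / r
        dhp_dgam = sn / (TWO_PI * r)
        J[1, 0] = dhp_dpsi + u * sn / r + (cs * cs - sn * sn) / r**2
        J[1, 1] = -cs / r
        J[1, 2] = dhp_dr + u * cs / r**2 - 2.0 * sn * cs / r**3
        J[1, 4] = dhp_dgam
        # f3 = cs, f4 = -sn
        J[2, 0] = -sn
        J[3, 0] = -cs
        # f5
        J[4, 0] = -(TWO_PI * cs / r) * cphi * (1.0 + Gam) + 2.0 * PI_ND * math.pi * r * cs
        J[4, 1] = TWO_PI * (h - cphi)
        J[4, 2] = TWO_PI * (sn / r**2) * cphi * (1.0 + Gam) + 2.0 * PI_ND * math.pi * sn
        Jp = np.zeros((5, m))
        Jp[1] = -cs / (TWO_PI * r)
        return J, Jp

    return rhs, jac


def _apex_residuals(ya: np.ndarray, fa: float, nd: _NDParams, s0: float) -> tuple[float, float]:
    """Residuals of the apex matching conditions at the cutoff s0."""
    psi_a, u_a, r_a = ya[0], ya[1], ya[2]
    cphi = math.sin(psi_a) / r_a
    g_loc = (fa - TWO_PI * nd.Gamma * (cphi - nd.R0inv)) / TWO_PI
    g_bar = g_loc * (1.0 - nd.Gamma / 4.0)
    return (r_a - s0, u_a - cphi + 0.5 * g_bar)


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------


def _integrate_geometry(x: np.ndarray, psi: np.ndarray, S: float, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """(r, z) from ψ(x) on the normalized grid by cumulative trapezoid."""
    ds = (S - s0)
    cs, sn = np.cos(psi), np.sin(psi)
    r = s0 + np.concatenate([[0.0], np.cumsum(0.5 * (cs[1:] + cs[:-1]) * np.diff(x) * ds)])
    z_rev = np.concatenate([[0.0], np.cumsum(0.5 * (sn[::-1][1:] + sn[::-1][:-1]) * np.diff(x) * ds)])
    z = z_rev[::-1]
    return r, z


def _seed_bump(S: float, nd: _NDParams, opts: SolverOptions) -> tuple[np.ndarray, np.ndarray, float]:
    """Shallow-dome seed for small invaginations."""
    x = np.linspace(0.0, 1.0, opts.n_mesh)
    amp = min(1.1, 0.55 * S)
    psi = amp * np.sin(math.pi * x)
    r, z = _integrate_geometry(x, psi, S, opts.s0)
    y = np.vstack([psi, np.gradient(psi, x) / (S - opts.s0), r, z, np.zeros_like(x)])
    fa0 = 4.0 * math.pi * max(nd.base_slope, 0.3)
    return x, y, fa0


def _seed_tube(S: float, nd: _NDParams, opts: SolverOptions) -> tuple[np.ndarray, np.ndarray, float]:
    """Hemisphere-capped cylinder seed for long invaginations."""
    p_nd = ModelParams.from_nd(C0_nd=nd.C0, sigma_nd=nd.sigma,
                               Gamma_nd=nd.Gamma,
                               R0_nd=(1.0 / nd.R0inv) if nd.R0inv else 1.0)
    try:
        R_star, f_tube = tube_limit(p_nd)
        R_star /= p_nd.R_Pi
        f_tube /= p_nd.kappa / p_nd.R_Pi
    except Exception:
        R_star, f_tube = 1.0, 1.5 * math.pi
    s_cap = 0.5 * math.pi * R_star
    if S < 2.5 * s_cap:
        return _seed_bump(S, nd, opts)
    x = np.linspace(0.0, 1.0, max(opts.n_mesh, 121))
    s = opts.s0 + x * (S - opts.s0)
    psi = np.empty_like(s)
    s1, s2 = s_cap, S - s_cap
    m1, m2, m3 = s <= s1, (s > s1) & (s < s2), s >= s2
    psi[m1] = 0.5 * math.pi * s[m1] / s1
    psi[m2] = 0.5 * math.pi
    psi[m3] = 0.5 * math.pi * (S - s[m3]) / s_cap
    r, z = _integrate_geometry(x, psi, S, opts.s0)
    y = np.vstack([psi, np.gradient(psi, x) / (S - opts.s0), r, z, np.zeros_like(x)])
    return x, y, f_tube


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ShapeSolution:
    """A converged equilibrium shape with its force, observables and energies.

    All public fields are in physical units (nm, pN, pN·nm).  ``nd`` keeps
    the raw nondimensional collocation output for warm starts.
    """

    profile: ShapeProfile
    params: ModelParams
    f_a: float
    observables: GeometricObservables
    energies: EnergyBreakdown
    residual: float
    converged: bool
    nd: dict = field(repr=False, default_factory=dict)

    @property
    def L(self) -> float:
        return self.observables.L


@dataclass
class Branch:
    """One continuation branch of equilibria, ordered by arclength S."""

    S: np.ndarray
    L: np.ndarray
    f_a: np.ndarray
    E_deform: np.ndarray
    neck_radius: np.ndarray
    branch_id: int = 0
    termination: str = "completed"

    @property
    def stable(self) -> np.ndarray:
        """Stability flag: dL/dS > 0 along the branch (fold criterion)."""
        dL = np.gradient(self.L, np.arange(self.L.size))
        return dL > 0

    def folds(self) -> list[tuple[float, float]]:
        dL = np.diff(self.L)
        out = []
        for i in range(1, dL.size):
            if dL[i - 1] * dL[i] < 0:
                out.append((float(self.L[i]), float(self.f_a[i])))
        return out


@dataclass
class ForceLengthCurve:
    """Force–length continuation output: one or two branches plus folds."""

    branches: list[Branch]
    params: ModelParams
    L_range: tuple[float, float]

    @property
    def fold_points(self) -> list[tuple[float, float]]:
        return [p for b in self.branches for p in b.folds()]

    def all_points(self) -> tuple[np.ndarray, np.ndarray]:
        L = np.concatenate([b.L for b in self.branches])
        f = np.concatenate([b.f_a for b in self.branches])
        return L, f

    def max_force(self) -> tuple[float, float]:
        L, f = self.all_points()
        i = int(np.argmax(f))
        return float(L[i]), float(f[i])

    def to_frame(self):
        import pandas as pd

        rows = []
        for b in self.branches:
            st = b.stable
            for j in range(b.S.size):
                rows.append(
                    dict(branch_id=b.branch_id, L_nm=b.L[j], fa_pN=b.f_a[j],
                         E_pNnm=b.E_deform[j], neck_nm=b.neck_radius[j],
                         stable=bool(st[j]))
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RigidityProfile:
    """Tip-stiff / base-soft rigidity pattern of a heterogeneous coat.

    kappa varies with the membrane area a(s) accumulated from the apex:
    kappa = kappa_tip within the tip cap of area A_tip, decaying to
    kappa_min over a transition of arclength width w (realized as a tanh
    in area of width 2*pi*R_Pi*w).
    """

    kappa_tip: float
    kappa_min: float
    A_tip: float
    w: float

    def __post_init__(self) -> None:
        if self.kappa_min > self.kappa_tip:
            raise ValueError("kappa_min must be <= kappa_tip")
        if self.A_tip <= 0 or self.w <= 0:
            raise ValueError("A_tip and w must be > 0")


# ---------------------------------------------------------------------------
# core solve (homogeneous)
# ---------------------------------------------------------------------------


def _solve_nd(
    nd: _NDParams,
    mode: str,
    *,
    L: float | None = None,
    fa: float | None = None,
    S: float | None = None,
    guess: tuple[np.ndarray, np.ndarray, list[float]] | None = None,
    opts: SolverOptions = SolverOptions(),
    pseudo: tuple[float, float, float, float, float] | None = None,
):
    """Solve the nondimensional BVP in one of four modes.

    mode = "height":    L prescribed, unknowns p = (S, f_a)
    mode = "force":     f_a prescribed, unknowns p = (S,)
    mode = "arclength": S prescribed, unknowns p = (f_a,)
    mode = "pseudo":    pseudo-arclength step, unknowns p = (S, f_a)
    """
    rhs, rjac = _rhs_factory(nd)
    s0 = opts.s0
    slope = nd.base_slope
    Gam, R0i = nd.Gamma, nd.R0inv
    # coefficients of the apex force-balance boundary row
    apex_cphi_coef = -1.0 - 0.5 * (1.0 - Gam / 4.0) * Gam
    apex_fa_coef = 0.5 * (1.0 - Gam / 4.0) / TWO_PI

    def _apex_jac_rows(ya, fav, n_bc, n_p, i_fa):
        """d(apex rows)/d ya and /d p; rows 0 (radius) and 1 (force)."""
        dya = np.zeros((n_bc, 5))
        dp = np.zeros((n_bc, n_p))
        dya[0, 2] = 1.0
        sn_a, cs_a = math.sin(ya[0]), math.cos(ya[0])
        ra = ya[2]
        dya[1, 0] = apex_cphi_coef * cs_a / ra
        dya[1, 1] = 1.0
        dya[1, 2] = -apex_cphi_coef * sn_a / ra**2
        if i_fa is not None:
            dp[1, i_fa] = apex_fa_coef
        return dya, dp

    def _base_rows(dya, start):
        dyb = np.zeros_like(dya)
        dyb[start, 0] = 1.0      # psi(S) = 0
        dyb[start + 1, 3] = 1.0  # z(S) = 0
        dyb[start + 2, 4] = 1.0  # gamma(S) = 0
        dyb[start + 3, 1] = 1.0  # u(S) + slope = 0
        return dyb

    if mode == "height":
        if L is None:
            raise ValueError("height mode needs L")

        def fun(x, y, p):
            Sv, fav = p
            return (Sv - s0) * rhs(y, fav)

        def fun_jac(x, y, p):
            Sv, fav = p
            J, Jp = rjac(y, fav)
            df_dp = np.empty((5, 2, y.shape[1]))
            df_dp[:, 0, :] = rhs(y, fav)
            df_dp[:, 1, :] = (Sv - s0) * Jp
            return (Sv - s0) * J, df_dp

        def bc(ya, yb, p):
            Sv, fav = p
            a1, a2 = _apex_residuals(ya, fav, nd, s0)
            return np.array([a1, a2, ya[3] - L,
                             yb[0], yb[3], yb[4], yb[1] + slope])

        def bc_jac(ya, yb, p):
            dya, dp = _apex_jac_rows(ya, p[1], 7, 2, 1)
            dya[2, 3] = 1.0
            dyb = _base_rows(dya, 3)
            return dya, dyb, dp

    elif mode == "force":
        if fa is None:
            raise ValueError("force mode needs fa")

        def fun(x, y, p):
            (Sv,) = p
            return (Sv - s0) * rhs(y, fa)

        def fun_jac(x, y, p):
            (Sv,) = p
            J, Jp = rjac(y, fa)
            df_dp = rhs(y, fa)[:, None, :]
            return (Sv - s0) * J, df_dp

        def bc(ya, yb, p):
            a1, a2 = _apex_residuals(ya, fa, nd, s0)
            return np.array([a1, a2, yb[0], yb[3], yb[4], yb[1] + slope])

        def bc_jac(ya, yb, p):
            dya, dp = _apex_jac_rows(ya, fa, 6, 1, None)
            dyb = _base_rows(dya, 2)
            return dya, dyb, dp

    elif mode == "arclength":
        if S is None:
            raise ValueError("arclength mode needs S")

        def fun(x, y, p):
            (fav,) = p
            return (S - s0) * rhs(y, fav)

        def fun_jac(x, y, p):
            (fav,) = p
            J, Jp = rjac(y, fav)
            return (S - s0) * J, (S - s0) * Jp[:, None, :]

        def bc(ya, yb, p):
            (fav,) = p
            a1, a2 = _apex_residuals(ya, fav, nd, s0)
            return np.array([a1, a2, yb[0], yb[3], yb[4], yb[1] + slope])

        def bc_jac(ya, yb, p):
            dya, dp = _apex_jac_rows(ya, p[0], 6, 1, 0)
            dyb = _base_rows(dya, 2)
            return dya, dyb, dp

    elif mode == "pseudo":
        # pseudo-arclength step: both S and f_a free, closed by the secant
        # plane constraint t . ((S, fa) - (S_prev, fa_prev)) = dtau
        if pseudo is None:
            raise ValueError("pseudo mode needs the constraint tuple")
        S_prev, fa_prev, tS, tfa, dtau = pseudo

        def fun(x, y, p):
            Sv, fav = p
            return (Sv - s0) * rhs(y, fav)

        def fun_jac(x, y, p):
            Sv, fav = p
            J, Jp = rjac(y, fav)
            df_dp = np.empty((5, 2, y.shape[1]))
            df_dp[:, 0, :] = rhs(y, fav)
            df_dp[:, 1, :] = (Sv - s0) * Jp
            return (Sv - s0) * J, df_dp

        def bc(ya, yb, p):
            Sv, fav = p
            a1, a2 = _apex_residuals(ya, fav, nd, s0)
            return np.array([a1, a2,
                             yb[0], yb[3], yb[4], yb[1] + slope,
                             tS * (Sv - S_prev) + tfa * (fav - fa_prev) - dtau])

        def bc_jac(ya, yb, p):
            dya, dp = _apex_jac_rows(ya, p[1], 7, 2, 1)
            dyb = _base_rows(dya, 2)
            dp[6, 0] = tS
            dp[6, 1] = tfa
            return dya, dyb, dp

    else:  # pragma: no cover
        raise ValueError(f"unknown mode {mode!r}")

    if guess is None:
        S_guess = S if S is not None else max(1.2, 1.45 * (L or 1.0) + 1.0)
        x, y, fa_guess = _seed_bump(S_guess, nd, opts)
    else:
        x, y, (S_guess, fa_guess) = guess[0], guess[1], list(guess[2])
        if x.size > opts.guess_max_nodes:
            xi = np.linspace(0.0, 1.0, opts.guess_max_nodes)
            y = np.vstack([np.interp(xi, x, yi) for yi in y])
            x = xi

    if mode == "height":
        p0 = [S_guess, fa if fa is not None else fa_guess]
    elif mode == "pseudo":
        p0 = [S_guess, fa_guess]
    elif mode == "force":
        p0 = [S_guess]
    else:
        p0 = [fa_guess]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = solve_bvp(fun, bc, x, y, p=p0, tol=opts.tol,
                        fun_jac=fun_jac, bc_jac=bc_jac,
                        max_nodes=opts.max_nodes, verbose=0)
    return sol


def _package(sol, nd: _NDParams, params: ModelParams, mode: str,
             fa_fixed: float | None, S_fixed: float | None,
             opts: SolverOptions) -> ShapeSolution:
    R = params.R_Pi
    f_unit = params.kappa / R  # nondimensional force unit in pN
    if mode in ("height", "pseudo"):
        S_nd, fa_nd = float(sol.p[0]), float(sol.p[1])
    elif mode == "force":
        S_nd, fa_nd = float(sol.p[0]), float(fa_fixed)
    else:
        S_nd, fa_nd = float(S_fixed), float(sol.p[0])
    x = sol.x
    psi, u, r, z, gam = sol.y
    s = opts.s0 + x * (S_nd - opts.s0)
    prof = ShapeProfile(s=s * R, r=r * R, z=z * R, psi=psi.copy())
    f_a = fa_nd * f_unit
    en = evaluate_energy(prof, params, f_a=f_a, min_nodes=4)
    obs = geometric_observables(prof, R_Pi=R)
    return ShapeSolution(
        profile=prof,
        params=params,
        f_a=f_a,
        observables=obs,
        energies=en,
        residual=float(np.max(sol.rms_residuals)) if sol.rms_residuals.size else math.nan,
        converged=bool(sol.success),
        nd=dict(x=x.copy(), y=sol.y.copy(), S=S_nd, fa=fa_nd,
                L=float(z[0]), mode=mode),
    )


def _guess_from(sol: ShapeSolution) -> tuple[np.ndarray, np.ndarray, list[float]]:
    ndd = sol.nd
    return ndd["x"], ndd["y"], [ndd["S"], ndd["fa"]]


def solve_shape(
    params: ModelParams,
    L: float | None = None,
    f_a: float | None = None,
    S: float | None = None,
    options: SolverOptions | None = None,
    warm_start: ShapeSolution | None = None,
    fallback: bool = True,
) -> ShapeSolution:
    """Solve for the equilibrium invagination at a prescribed target.

    Exactly one of ``L`` (height, nm), ``f_a`` (apical force, pN) or ``S``
    (total detached arclength, nm) must be given.  When ``L`` is imposed
    the conjugate force ``f_a`` is returned with the solution, and vice
    versa.  Raises :class:`NoEquilibriumError` when no equilibrium can be
    found (expected for heights inside the no-equilibrium gap of the
    strong-curvature regime).

    ``fallback=False`` skips the branch-walking rescue used after direct
    cold-start failures; continuation-style callers that probe for branch
    ends use this to fail fast.
    """
    opts = options or SolverOptions()
    nd = _NDParams.from_params(params)
    R = params.R_Pi
    ntargets = sum(t is not None for t in (L, f_a, S))
    if ntargets != 1:
        raise ValueError("give exactly one of L, f_a, S")

    if L is not None:
        mode, L_nd, fa_nd, S_nd = "height", L / R, None, None
    elif f_a is not None:
        mode, L_nd, fa_nd, S_nd = "force", None, f_a / (params.kappa / R), None
    else:
        mode, L_nd, fa_nd, S_nd = "arclength", None, None, S / R

    guesses = []
    if warm_start is not None:
        guesses.append(_guess_from(warm_start))
    guesses.append(None)
    if mode == "height" and L_nd is not None and L_nd > 2.0 and fallback:
        # long invaginations: capped-cylinder seed before the branch walk
        seed = _seed_tube(L_nd + 2.0, nd, opts)
        guesses.append((seed[0], seed[1], [L_nd + 2.0, seed[2]]))

    last = None
    for guess in guesses:
        sol = _solve_nd(nd, mode, L=L_nd, fa=fa_nd, S=S_nd, guess=guess, opts=opts)
        last = sol
        if sol.success:
            return _package(sol, nd, params, mode, fa_nd, S_nd, opts)

    # cold start failed: walk the branch from the flat state (and from the
    # tube side) to reach the target; a height inside the gap is unreachable.
    if not fallback:
        raise NoEquilibriumError(
            f"no equilibrium found (mode {mode!r}, fast path)")
    if mode == "height":
        got = _walk_to_height(nd, params, L_nd, opts)
        if got is not None:
            return got
        raise NoEquilibriumError(
            f"no equilibrium found at L = {L} nm "
            f"(C0_nd={nd.C0:.3f}: possibly inside the no-equilibrium gap)")
    raise SolverError(f"BVP failed in mode {mode!r}: {last.message if last else 'n/a'}")


def _walk_to_height(nd: _NDParams, params: ModelParams, L_nd: float,
                    opts: SolverOptions) -> ShapeSolution | None:
    """Arclength continuation until the target height is bracketed."""
    for direction in ("up", "down"):
        sols = []
        if direction == "up":
            S_grid = None
            S, S_stop = 0.7, max(4.0 * L_nd + 6.0, 10.0)
            seed = _seed_bump(S, nd, opts)
        else:
            S = max(2.0 * L_nd + 3.0, 6.0)
            S_stop = 0.7
            seed = _seed_tube(S, nd, opts)
        guess = (seed[0], seed[1], [S, seed[2]])
        dS = 0.25 if direction == "up" else -0.25
        prevL = None
        while (S < S_stop) if direction == "up" else (S > S_stop):
            sol = _solve_nd(nd, "arclength", S=S, guess=guess, opts=opts)
            if not sol.success:
                if abs(dS) < 5e-3:
                    break
                S -= dS
                dS *= 0.4
                S += dS
                continue
            Lh = float(sol.y[3][0])
            guess = (sol.x, sol.y, [S, float(sol.p[0])])
            if prevL is not None and (prevL - L_nd) * (Lh - L_nd) <= 0:
                # bracketed: refine with a height-mode solve warm started here
                hsol = _solve_nd(nd, "height", L=L_nd,
                                 guess=(sol.x, sol.y, [S, float(sol.p[0])]),
                                 opts=opts)
                if hsol.success:
                    return _package(hsol, nd, params, "height", None, None, opts)
            prevL = Lh
            S += dS
    return None


# ---------------------------------------------------------------------------
# branch tracing
# ---------------------------------------------------------------------------


def _tube_start(nd: _NDParams, S_top: float, opts: SolverOptions):
    """Converged solution at large S, seeding the upper/tube branch.

    Tries the capped-cylinder seed directly; if Newton rejects it (strong
    curvature or BAR parameters), reaches the target by homotopy from the
    bare-membrane tube (C0 = Gamma = 0), ramping the parameters at fixed
    S with adaptive steps.  Several anchor arclengths are tried: at strong
    curvature the long-S spheroids have necks below the numerically
    resolvable closure scale, while moderate S remains reachable.
    """
    seed = _seed_tube(S_top, nd, opts)
    sol = _solve_nd(nd, "arclength", S=S_top, guess=(seed[0], seed[1], [S_top, seed[2]]),
                    opts=opts)
    if sol.success:
        return sol, S_top
    for S_try in (S_top, 0.75 * S_top, 0.6 * S_top, 0.45 * S_top):
        nd0 = _NDParams(C0=0.0, sigma=nd.sigma, Gamma=0.0, R0inv=0.0)
        seed = _seed_tube(S_try, nd0, opts)
        sol = _solve_nd(nd0, "arclength", S=S_try,
                        guess=(seed[0], seed[1], [S_try, seed[2]]), opts=opts)
        if not sol.success:
            continue
        w, dw, ok = 0.0, 0.125, True
        while w < 1.0 - 1e-9:
            wn = min(w + dw, 1.0)
            nd_w = _NDParams(C0=wn * nd.C0, sigma=nd.sigma,
                             Gamma=wn * nd.Gamma, R0inv=nd.R0inv)
            s2 = _solve_nd(nd_w, "arclength", S=S_try,
                           guess=(sol.x, sol.y, [S_try, float(sol.p[0])]),
                           opts=opts)
            if s2.success:
                sol, w = s2, wn
                if s2.niter <= 4:
                    dw = min(dw * 1.5, 0.2)
            else:
                dw *= 0.4
                if dw < 1e-3:
                    ok = False
                    break
        if ok:
            return sol, S_try
    return None, S_top


def _continue_branch(nd: _NDParams, params: ModelParams, opts: SolverOptions,
                     S_start: float, direction: float, seed_kind: str,
                     L_max_nd: float, branch_id: int,
                     dtau0: float = 0.15, dtau_min: float = 1.5e-3,
                     dtau_max: float = 0.35, fa_weight: float = 0.5,
                     max_points: int = 300,
                     S_cap: float | None = None) -> Branch:
    """Pseudo-arclength continuation in (S, f_a) from a seeded start point.

    ``direction`` is the initial sign of dS.  The secant tangent through
    the last two accepted points closes each step; folds in either S or
    f_a are traversed.  The branch terminates at the requested height
    range boundary, at neck closure, or when the step collapses.
    """
    R = params.R_Pi
    f_unit = params.kappa / R
    if S_cap is None:
        S_cap = 2.6 * L_max_nd + 9.0

    # first point: plain fixed-S solve
    if seed_kind == "bump":
        seed = _seed_bump(S_start, nd, opts)
        sol = _solve_nd(nd, "arclength", S=S_start,
                        guess=(seed[0], seed[1], [S_start, seed[2]]), opts=opts)
    elif seed_kind == "tube":
        sol, S_start = _tube_start(nd, S_start, opts)
    else:  # pre-converged (sol, S) handed in
        sol, S_start = seed_kind

    empty = Branch(S=np.empty(0), L=np.empty(0), f_a=np.empty(0),
                   E_deform=np.empty(0), neck_radius=np.empty(0),
                   branch_id=branch_id, termination="no_start")
    if sol is None or not sol.success:
        return empty

    rows: list[tuple[float, float, float, float, float]] = []

    def record(S, sol):
        fa_nd = float(sol.p[0]) if len(sol.p) == 1 else float(sol.p[1])
        L_nd = float(sol.y[3][0])
        neck = _neck_nd(sol.y[0], sol.y[2])
        E_nd = _deform_energy_nd(sol, nd, opts, S)
        rows.append((S, L_nd, fa_nd, E_nd, neck))
        return fa_nd, L_nd, neck

    S = S_start
    fa, L_nd, neck = record(S, sol)
    tS, tfa = direction, 0.0
    dtau = dtau0
    termination = "completed"
    guess = (sol.x, sol.y, None)
    while len(rows) < max_points:
        step = _solve_nd(nd, "pseudo", guess=(guess[0], guess[1],
                                              [S + tS * dtau, fa + tfa * dtau]),
                         opts=opts,
                         pseudo=(S, fa, tS, fa_weight * tfa, dtau))
        if not step.success:
            if dtau <= dtau_min:
                termination = "step_failure"
                break
            dtau *= 0.35
            continue
        S_new, fa_new = float(step.p[0]), float(step.p[1])
        fa_chk, L_new, neck = record(S_new, step)
        # secant tangent for the next step, normalized
        dS, dfa = S_new - S, fa_new - fa
        nrm = math.hypot(dS, fa_weight * dfa)
        if nrm > 0:
            tS, tfa = dS / nrm, dfa / nrm
        S, fa = S_new, fa_new
        guess = (step.x, step.y, None)
        if step.niter <= 4:
            dtau = min(dtau * 1.6, dtau_max)
        elif step.niter <= 6:
            dtau = min(dtau * 1.15, dtau_max)
        # termination checks
        if L_new > L_max_nd * 1.03 and len(rows) > 2 and rows[-1][1] > rows[-2][1]:
            break
        if direction < 0 and L_new < 0.12:
            break
        if neck < 1e-2:
            termination = "neck_closure"
            break
        if S > S_cap or S < 0.5:
            break
    else:
        termination = "max_points"
    if not rows:
        return empty
    arr = np.array(rows)
    return Branch(
        S=arr[:, 0] * R, L=arr[:, 1] * R, f_a=arr[:, 2] * f_unit,
        E_deform=arr[:, 3] * params.kappa, neck_radius=arr[:, 4] * R,
        branch_id=branch_id, termination=termination,
    )


def _neck_nd(psi: np.ndarray, r: np.ndarray) -> float:
    i1 = int(np.argmax(psi))
    return float(r[i1:].min())


def _deform_energy_nd(sol, nd: _NDParams, opts: SolverOptions, S: float) -> float:
    psi, u, r, z, gam = sol.y
    s = opts.s0 + sol.x * (S - opts.s0)
    sn = np.sin(psi)
    cphi = sn / r
    h = u + cphi - nd.C0
    ring = TWO_PI * r
    E = np.trapezoid(0.5 * h**2 * ring, s)
    E += nd.sigma * np.trapezoid(ring, s)
    E += PI_ND * np.trapezoid(math.pi * r**2 * sn, s)
    if nd.Gamma > 0:
        E += np.trapezoid(0.5 * nd.Gamma * (cphi - nd.R0inv) ** 2 * ring, s)
    return float(E)


def trace_branch(
    params: ModelParams,
    L_range: tuple[float, float] | None = None,
    options: SolverOptions | None = None,
    dS0: float = 0.15,
    max_points: int = 300,
) -> ForceLengthCurve:
    """Trace the equilibrium force–length curve over a height range.

    Two continuations are run: one seeded from the flat state (S small)
    and one from the long-tube asymptote (S large), so that disconnected
    branches in the gap regime are both captured.  If the flat-seeded
    branch reaches the top of the range the curve is connected and a
    single branch is returned.
    """
    opts = options or SolverOptions()
    nd = _NDParams.from_params(params)
    R = params.R_Pi
    if L_range is None:
        L_range = (0.0, 6.0 * R)
    L_max_nd = L_range[1] / R

    lower = _continue_branch(nd, params, opts, S_start=0.6, direction=+1.0,
                             seed_kind="bump", L_max_nd=L_max_nd,
                             branch_id=0, dtau0=dS0, max_points=max_points)
    connected = lower.L.size > 0 and lower.L.max() / R >= L_max_nd * 0.99 \
        and lower.termination == "completed"
    branches = [lower]
    if not connected:
        S_top = L_max_nd + 3.5
        start, S_anchor = _tube_start(nd, S_top, opts)
        if start is not None and start.success:
            down = _continue_branch(nd, params, opts, S_start=S_anchor,
                                    direction=-1.0, seed_kind=(start, S_anchor),
                                    L_max_nd=L_max_nd, branch_id=1, dtau0=dS0,
                                    max_points=max_points)
            parts = [down]
            if float(start.y[3][0]) < L_max_nd * 0.99:
                up = _continue_branch(nd, params, opts, S_start=S_anchor,
                                      direction=+1.0, seed_kind=(start, S_anchor),
                                      L_max_nd=L_max_nd, branch_id=1, dtau0=dS0,
                                      max_points=max_points)
                parts.append(up)
            S_all = np.concatenate([p.S for p in parts if p.S.size])
            if S_all.size:
                L_all = np.concatenate([p.L for p in parts if p.S.size])
                f_all = np.concatenate([p.f_a for p in parts if p.S.size])
                E_all = np.concatenate([p.E_deform for p in parts if p.S.size])
                n_all = np.concatenate([p.neck_radius for p in parts if p.S.size])
                order = np.argsort(S_all)
                term = down.termination if down.S.size else "no_start"
                branches.append(Branch(S=S_all[order], L=L_all[order],
                                       f_a=f_all[order], E_deform=E_all[order],
                                       neck_radius=n_all[order],
                                       branch_id=1, termination=term))
    return ForceLengthCurve(branches=branches, params=params, L_range=L_range)


# ---------------------------------------------------------------------------
# heterogeneous rigidity
# ---------------------------------------------------------------------------


def _kappa_of_area(rig_nd: tuple[float, float, float]):
    """kappa(a) and kappa'(a) in tip-rigidity units; tanh step in area."""
    kmin, A_tip, wA = rig_nd

    def kap(a):
        return kmin + (1.0 - kmin) * 0.5 * (1.0 - np.tanh((a - A_tip) / wA))

    def kapp(a):
        return -(1.0 - kmin) * 0.5 / wA / np.cosh((a - A_tip) / wA) ** 2

    return kap, kapp


def solve_heterogeneous(
    params: ModelParams,
    rigidity: RigidityProfile,
    L: float | None = None,
    S: float | None = None,
    options: SolverOptions | None = None,
    warm_start: ShapeSolution | None = None,
) -> ShapeSolution:
    """Equilibrium shape with a stiff tip and a softer base.

    ``params.kappa`` must equal ``rigidity.kappa_tip``; the rigidity decays
    from kappa_tip to kappa_min once the membrane area accumulated from
    the apex exceeds ``A_tip``.  With kappa_min = kappa_tip this reduces
    to :func:`solve_shape`.  Raises :class:`NoEquilibriumError` when the
    base is too soft to support an equilibrium (rigidity-driven
    instability).
    """
    if abs(params.kappa - rigidity.kappa_tip) > 1e-9 * params.kappa:
        raise ValueError("params.kappa must equal rigidity.kappa_tip")
    if rigidity.kappa_min == rigidity.kappa_tip:
        return solve_shape(params, L=L, S=S, options=options, warm_start=warm_start)
    opts = options or SolverOptions()
    nd = _NDParams.from_params(params)
    R = params.R_Pi
    rig_nd = (rigidity.kappa_min / rigidity.kappa_tip,
              rigidity.A_tip / R**2,
              TWO_PI * rigidity.w / R)
    kap, kapp = _kappa_of_area(rig_nd)
    C0, sig, Gam, R0i = nd.C0, nd.sigma, nd.Gamma, nd.R0inv
    s0 = opts.s0

    def rhs(y, fa):
        psi, u, r, z, gam, a, mu = y
        sn, cs = np.sin(psi), np.cos(psi)
        k = kap(a)
        kp = kapp(a)
        cphi = sn / r
        h = u + cphi - C0
        b = cphi - R0i
        hp = (TWO_PI * Gam * cs * b + PI_ND * math.pi * r**2 * cs
              + gam * sn - fa * cs) / (TWO_PI * k * r) - TWO_PI * kp * r * h / k
        up = hp - u * cs / r + sn * cs / r**2
        gamp = (TWO_PI * (0.5 * k * h**2 + 0.5 * Gam * b**2 + sig)
                - TWO_PI * cphi * (k * h + Gam * b)
                + 2.0 * PI_ND * math.pi * r * sn
                - TWO_PI * mu)
        mup = math.pi * r * kp * h**2
        return np.vstack([u, up, cs, -sn, gamp, TWO_PI * r, mup])

    def base_slope(a_end):
        kend = kap(a_end)
        return np.sqrt(C0**2 + 2.0 * sig / kend + Gam * R0i**2 / kend)

    def apex_res(ya, fa):
        psi_a, u_a, r_a = ya[0], ya[1], ya[2]
        cphi = np.sin(psi_a) / r_a
        ktip = kap(0.0)
        g_loc = (fa - TWO_PI * Gam * (cphi - R0i)) / (TWO_PI * ktip)
        g_bar = g_loc * (1.0 - Gam / (4.0 * ktip))
        return (r_a - s0, u_a - cphi + 0.5 * g_bar)

    if L is not None:
        L_nd = L / R

        def fun(x, y, p):
            Sv, fav = p
            return (Sv - s0) * rhs(y, fav)

        def bc(ya, yb, p):
            Sv, fav = p
            a1, a2 = apex_res(ya, fav)
            return np.array([a1, a2, ya[3] - L_nd, ya[5] - math.pi * s0**2,
                             yb[0], yb[3], yb[4], yb[1] + base_slope(yb[5]),
                             yb[6]])
        nparams = 2
    elif S is not None:
        S_nd = S / R

        def fun(x, y, p):
            (fav,) = p
            return (S_nd - s0) * rhs(y, fav)

        def bc(ya, yb, p):
            (fav,) = p
            a1, a2 = apex_res(ya, fav)
            return np.array([a1, a2, ya[5] - math.pi * s0**2,
                             yb[0], yb[3], yb[4], yb[1] + base_slope(yb[5]),
                             yb[6]])
        nparams = 1
    else:
        raise ValueError("give L or S")

    # seed: homogeneous solution at kappa_tip, then ramp kappa_min down
    ratios = np.linspace(1.0, rig_nd[0], 6)[1:]
    if warm_start is not None and warm_start.nd.get("het"):
        x0, y0 = warm_start.nd["x"], warm_start.nd["y"]
        p0 = ([warm_start.nd["S"], warm_start.nd["fa"]] if L is not None
              else [warm_start.nd["fa"]])
        ramp = [(rig_nd[0], (x0, y0, p0))]
    else:
        homo = solve_shape(params, L=L, S=S, options=opts)
        x0 = homo.nd["x"]
        psi, u, r, z, gam = homo.nd["y"]
        s = s0 + x0 * (homo.nd["S"] - s0)
        a = np.concatenate([[math.pi * s0**2],
                            math.pi * s0**2 + np.cumsum(
                                0.5 * TWO_PI * (r[1:] + r[:-1]) * np.diff(s))])
        y0 = np.vstack([psi, u, r, z, gam, a, np.zeros_like(x0)])
        p0 = ([homo.nd["S"], homo.nd["fa"]] if L is not None
              else [homo.nd["fa"]])
        ramp = [(rr, None) for rr in ratios]
        ramp[0] = (ratios[0], (x0, y0, p0))

    sol = None
    guess = ramp[0][1] if ramp[0][1] is not None else (x0, y0, p0)
    for rr, g in ramp:
        kap, kapp = _kappa_of_area((rr, rig_nd[1], rig_nd[2]))
        if g is not None:
            guess = g
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = solve_bvp(fun, bc, guess[0], guess[1], p=guess[2],
                            tol=opts.tol, max_nodes=opts.max_nodes, verbose=0)
        if not sol.success:
            raise NoEquilibriumError(
                f"heterogeneous solve lost equilibrium at kappa_min/kappa_tip={rr:.3f} "
                "(rigidity-driven instability)")
        guess = (sol.x, sol.y, list(sol.p))
    # restore requested profile closure state
    kap, kapp = _kappa_of_area(rig_nd)

    if L is not None:
        S_nd_out, fa_nd = float(sol.p[0]), float(sol.p[1])
    else:
        S_nd_out, fa_nd = S / R, float(sol.p[0])
    x = sol.x
    psi, u, r, z, gam, a, mu = sol.y
    s = s0 + x * (S_nd_out - s0)
    prof = ShapeProfile(s=s * R, r=r * R, z=z * R, psi=psi.copy())
    f_unit = params.kappa / R
    f_a = fa_nd * f_unit
    en = evaluate_energy(prof, params, f_a=f_a, min_nodes=4)
    obs = geometric_observables(prof, R_Pi=R)
    return ShapeSolution(
        profile=prof, params=params, f_a=f_a, observables=obs, energies=en,
        residual=float(np.max(sol.rms_residuals)) if sol.rms_residuals.size else math.nan,
        converged=bool(sol.success),
        nd=dict(x=x.copy(), y=sol.y.copy(), S=S_nd_out, fa=fa_nd,
                L=float(z[0]), mode="het", het=True),
    )
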