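"""Physical data model and energetics of pressurized membrane invaginations.

Units are fixed throughout the package: lengths in nm, forces in pN,
energies in pN·nm, tension sigma in pN/nm, pressure Pi in pN/nm^2
(1 pN/nm^2 = 1 MPa), curvatures in 1/nm.  The thermal energy constant
is ``KBT = 4.1`` pN·nm.

The invagination shape is controlled by two intrinsic length scales:

* ``R_Pi = (kappa / 2 Pi)**(1/3)`` -- the pressure–rigidity width, the
  natural radius of an invagination pushed against a wall by turgor;
* ``lambda = sqrt(kappa / 2 sigma)`` -- the tension–rigidity width.

and by the force scale ``f_Pi = 4 pi Pi R_Pi**2 = 2 pi kappa / R_Pi``.
Internally the solver works in nondimensional units kappa = 1, R_Pi = 1
(hence Pi = 1/2, f_Pi = 2 pi), which makes every result a function of
the reduced parameters ``sigma_nd = sigma R_Pi^2 / kappa``,
``C0_nd = C0 R_Pi``, ``Gamma_nd = Gamma / kappa`` and ``R0_nd = R0 / R_Pi``
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

KBT = 4.1  # pN·nm

__all__ = [
    "KBT",
    "ModelParams",
    "DerivedScales",
    "ShapeProfile",
    "EnergyBreakdown",
    "GeometricObservables",
    "derived_scales",
    "evaluate_energy",
    "geometric_observables",
    "initiation_force",
    "tube_limit",
    "quasistatic_timescale",
    "coat_adhesion_force",
]


class InvalidParamsError(ValueError):
    """Raised when physical parameters violate their invariants."""


class ResolutionError(ValueError):
    """Raised when a profile grid is too coarse for reliable quadrature."""


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the coated membrane under turgor.

    Parameters
    ----------
    kappa : float
        Bending rigidity of the (coated) membrane [pN·nm].
    sigma : float
        Membrane tension [pN/nm].
    Pi : float
        Turgor pressure difference across the membrane [pN/nm^2].
    C0 : float
        Isotropic spontaneous *total* curvature imposed by the coat [1/nm].
    Gamma : float
        Rigidity of the anisotropic (BAR-domain) curvature term [pN·nm].
    R0 : float
        Preferred azimuthal radius of curvature of the BAR coat [nm].
    """

    kappa: float
    sigma: float = 0.0
    Pi: float = 1.0
    C0: float = 0.0
    Gamma: float = 0.0
    R0: float = 1.0
    kBT: float = field(default=KBT)

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise InvalidParamsError(f"kappa must be > 0, got {self.kappa}")
        if not (self.Pi > 0):
            raise InvalidParamsError(f"Pi must be > 0, got {self.Pi}")
        if self.sigma < 0:
            raise InvalidParamsError(f"sigma must be >= 0, got {self.sigma}")
        if self.Gamma < 0:
            raise InvalidParamsError(f"Gamma must be >= 0, got {self.Gamma}")
        if self.Gamma > 0 and not (self.R0 > 0):
            raise InvalidParamsError("R0 must be > 0 when Gamma > 0")

    # --- nondimensional view -------------------------------------------------

    @property
    def R_Pi(self) -> float:
        return (self.kappa / (2.0 * self.Pi)) ** (1.0 / 3.0)

    @property
    def f_Pi(self) -> float:
        return 4.0 * math.pi * self.Pi * self.R_Pi**2

    @property
    def sigma_nd(self) -> float:
        return self.sigma * self.R_Pi**2 / self.kappa

    @property
    def C0_nd(self) -> float:
        return self.C0 * self.R_Pi

    @property
    def Gamma_nd(self) -> float:
        return self.Gamma / self.kappa

    @property
    def R0_nd(self) -> float:
        return self.R0 / self.R_Pi

    @classmethod
    def from_nd(
        cls,
        C0_nd: float = 0.0,
        sigma_nd: float = 0.0,
        Gamma_nd: float = 0.0,
        R0_nd: float = 1.0,
        R_Pi: float = 1.0,
        Pi: float = 0.5,
    ) -> "ModelParams":
        """Build physical parameters from reduced ones at a given scale.

        ``R_Pi`` and ``Pi`` fix the dimensional scale; the shape of every
        solution depends only on the reduced parameters.
        """
        kappa = 2.0 * Pi * R_Pi**3
        return cls(
            kappa=kappa,
            sigma=sigma_nd * kappa / R_Pi**2,
            Pi=Pi,
            C0=C0_nd / R_Pi,
            Gamma=Gamma_nd * kappa,
            R0=R0_nd * R_Pi,
        )

    def rescaled(self, c: float) -> "ModelParams":
        """Return params with kappa and Pi both multiplied by ``c``.

        Leaves all reduced parameters (and hence all shapes) unchanged.
        """
        return replace(
            self,
            kappa=c * self.kappa,
            Pi=c * self.Pi,
            sigma=c * self.sigma,
            Gamma=c * self.Gamma,
        )


@dataclass(frozen=True)
class DerivedScales:
    """Length and force scales derived from the physical parameters."""

    R_Pi: float  # pressure–rigidity length [nm]
    lam: float  # tension–rigidity length [nm]; inf when sigma = 0
    f_Pi: float  # force scale [pN]


def derived_scales(params: ModelParams) -> DerivedScales:
    """Compute R_Pi = (kappa/2Pi)^(1/3), lambda = sqrt(kappa/2sigma), f_Pi."""
    R_Pi = params.R_Pi
    lam = math.inf if params.sigma == 0 else math.sqrt(params.kappa / (2.0 * params.sigma))
    return DerivedScales(R_Pi=R_Pi, lam=lam, f_Pi=params.f_Pi)


@dataclass
class ShapeProfile:
    """Axisymmetric membrane profile, apex (s=0) to contact line (s=S).

    ``psi`` is the tangent angle measured from the wall plane, with
    dr/ds = cos(psi) and dz/ds = -sin(psi) going apex -> base, so a dome
    tip has dpsi/ds > 0 and the apex sits at z(0) = L, the base at z = 0.
    """

    s: np.ndarray
    r: np.ndarray
    z: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, float)
        self.r = np.asarray(self.r, float)
        self.z = np.asarray(self.z, float)
        self.psi = np.asarray(self.psi, float)
        if not (self.s.shape == self.r.shape == self.z.shape == self.psi.shape):
            raise ValueError("s, r, z, psi must have equal shapes")
        if self.s.ndim != 1 or self.s.size < 4:
            raise ValueError("profile needs at least 4 samples")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("arclength grid must be strictly increasing")

    @property
    def L(self) -> float:
        """Invagination height = apex elevation above the wall plane."""
        return float(self.z[0] - self.z[-1])

    @property
    def total_arclength(self) -> float:
        return float(self.s[-1] - self.s[0])

    def curvatures(self) -> tuple[np.ndarray, np.ndarray]:
        """Meridional (dpsi/ds) and azimuthal (sin psi / r) curvatures.

        The azimuthal curvature at the apex (r -> 0) is taken equal to the
        meridional one (regularity of an axisymmetric surface at its pole).
        """
        cm = np.gradient(self.psi, self.s)
        cphi = np.empty_like(cm)
        small = self.r <= 1e-12 * max(self.r.max(), 1.0)
        cphi[~small] = np.sin(self.psi[~small]) / self.r[~small]
        cphi[small] = cm[small]
        return cm, cphi

    def geometric_residual(self) -> float:
        """Max deviation of (dr/ds, dz/ds) from (cos psi, -sin psi)."""
        dr = np.gradient(self.r, self.s)
        dz = np.gradient(self.z, self.s)
        return float(
            max(np.abs(dr - np.cos(self.psi)).max(), np.abs(dz + np.sin(self.psi)).max())
        )


@dataclass(frozen=True)
class EnergyBreakdown:
    """Components of the invagination energy [pN·nm].

    ``F_total`` is the full functional including the pulling work
    ``-f_a L``; ``E_deform = F_total + f_a L`` is the deformation energy
    (bending + tension + pressure + BAR terms only).
    """

    E_bend: float
    E_tension: float
    E_pressure: float
    E_bar: float
    work: float

    @property
    def E_deform(self) -> float:
        return self.E_bend + self.E_tension + self.E_pressure + self.E_bar

    @property
    def F_total(self) -> float:
        return self.E_deform + self.work


@dataclass(frozen=True)
class GeometricObservables:
    L: float  # height [nm]
    V: float  # enclosed volume between membrane and wall plane [nm^3]
    S: float  # detached membrane area [nm^2]
    S0: float  # projected wall area out of contact, pi r_contact^2 [nm^2]
    neck_radius: float  # narrowest radius of the neck region [nm]
    tip_radius: float  # osculating radius at the apex [nm]


MIN_NODES_PER_RPI = 200.0


def _require_resolution(profile: ShapeProfile, R_Pi: float, min_nodes: int = 32) -> None:
    n = profile.s.size
    if n < min_nodes:
        raise ResolutionError(f"profile has {n} nodes, need at least {min_nodes}")


def evaluate_energy(
    profile: ShapeProfile,
    params: ModelParams,
    f_a: float = 0.0,
    min_nodes: int = 32,
) -> EnergyBreakdown:
    """Evaluate the energy components of a profile by trapezoid quadrature.

    E_bend = ∫ kappa/2 (c_m + c_phi - C0)^2 2 pi r ds,
    E_tension = sigma S, E_pressure = Pi V,
    E_bar = ∫ Gamma/2 (c_phi - 1/R0)^2 2 pi r ds, work = -f_a L.
    """
    _require_resolution(profile, params.R_Pi, min_nodes)
    if np.any(profile.r < -1e-9):
        raise ValueError("profile has negative radius")
    cm, cphi = profile.curvatures()
    r, s, psi = profile.r, profile.s, profile.psi
    ring = 2.0 * math.pi * r
    E_bend = float(np.trapezoid(0.5 * params.kappa * (cm + cphi - params.C0) ** 2 * ring, s))
    area = float(np.trapezoid(ring, s))
    E_tension = params.sigma * area
    V = float(np.trapezoid(math.pi * r**2 * np.sin(psi), s))
    E_pressure = params.Pi * V
    if params.Gamma > 0:
        E_bar = float(
            np.trapezoid(0.5 * params.Gamma * (cphi - 1.0 / params.R0) ** 2 * ring, s)
        )
    else:
        E_bar = 0.0
    return EnergyBreakdown(
        E_bend=E_bend,
        E_tension=E_tension,
        E_pressure=E_pressure,
        E_bar=E_bar,
        work=-f_a * profile.L,
    )


def _tip_radius(profile: ShapeProfile, window: float) -> float:
    """Osculating radius at the apex from a least-squares circle fit.

    Fits a circle to the mirrored tip points within ``window`` of arclength
    from the apex; this is the resolution-robust estimate of the paper's
    tip radius R_t (the pointwise apex curvature diverges logarithmically
    under a point force).
    """
    m = profile.s - profile.s[0] <= window
    if m.sum() < 4:
        m = np.zeros_like(m)
        m[: min(4, profile.s.size)] = True
    x = np.concatenate([-profile.r[m][::-1], profile.r[m]])
    y = np.concatenate([profile.z[m][::-1], profile.z[m]])
    # algebraic circle fit: x^2 + y^2 = 2 a x + 2 b y + c
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    a, b, c = sol
    return float(math.sqrt(max(c + a**2 + b**2, 0.0)))


def geometric_observables(profile: ShapeProfile, R_Pi: float | None = None) -> GeometricObservables:
    """Geometric observables of a profile.

    The neck radius is the minimum of r(s) from the point of steepest
    tangent (argmax psi) to the base: for overhanging shapes this is the
    true neck; for a tube it is the tube radius; for a shallow dome it
    degrades gracefully to a positive width near the inflection.
    """
    r, s, z, psi = profile.r, profile.s, profile.z, profile.psi
    if R_Pi is None:
        R_Pi = max(profile.L, r.max(), 1.0)
    ring = 2.0 * math.pi * r
    V = float(np.trapezoid(math.pi * r**2 * np.sin(psi), s))
    S = float(np.trapezoid(ring, s))
    i1 = int(np.argmax(psi))
    neck = float(r[i1:].min()) if i1 < r.size else float(r[-1])
    return GeometricObservables(
        L=profile.L,
        V=V,
        S=S,
        S0=math.pi * float(r[-1]) ** 2,
        neck_radius=neck,
        tip_radius=_tip_radius(profile, 0.7 * R_Pi),
    )


def initiation_force(params: ModelParams) -> float:
    """Apical force needed at vanishing invagination height.

    f_0 = 4 pi kappa sqrt(C0^2 + 2 sigma/kappa + Gamma/(kappa R0^2)),
    the L -> 0 limit of the equilibrium pulling force.  With
    sigma = Gamma = 0 this is the flat-membrane result f_0 = 4 pi kappa C0:
    spontaneous curvature does not lift the membrane but raises the force
    needed to start the invagination, because the rim must curve against C0.
    """
    D = params.C0**2 + 2.0 * params.sigma / params.kappa
    if params.Gamma > 0:
        D += params.Gamma / (params.kappa * params.R0**2)
    return 4.0 * math.pi * params.kappa * math.sqrt(D)


class NoTubeRegimeError(RuntimeError):
    """No interior minimum of the per-length tube energy exists."""


def tube_limit(params: ModelParams) -> tuple[float, float]:
    """Radius and asymptotic force of the long-tube (plateau) limit.

    Minimizes the per-unit-length energy of a cylinder of radius R,

        e(R) = pi kappa (1/R - C0)^2 R + 2 pi sigma R + Pi pi R^2
               [+ pi Gamma (1/R - 1/R0)^2 R],

    over R.  The minimizing radius R* is the asymptotic tube radius and
    e(R*) the plateau pulling force of a long invagination.
    """
    from scipy.optimize import minimize_scalar

    k, s_, P, C0 = params.kappa, params.sigma, params.Pi, params.C0

    def e(R: float) -> float:
        val = (
            math.pi * k * (1.0 / R - C0) ** 2 * R
            + 2.0 * math.pi * s_ * R
            + P * math.pi * R**2
        )
        if params.Gamma > 0:
            val += math.pi * params.Gamma * (1.0 / R - 1.0 / params.R0) ** 2 * R
        return val

    R_Pi = params.R_Pi
    res = minimize_scalar(e, bounds=(1e-3 * R_Pi, 50.0 * R_Pi), method="bounded",
                          options={"xatol": 1e-12 * R_Pi})
    R_star = float(res.x)
    if R_star <= 2e-3 * R_Pi or R_star >= 49.0 * R_Pi:
        raise NoTubeRegimeError("per-length energy has no interior minimum")
    return R_star, float(e(R_star))


def quasistatic_timescale(L: float, eta_m: float, f: float) -> float:
    """Viscous relaxation time L*eta_m/f for pulling a tube of length L.

    ``L`` in nm, ``eta_m`` (membrane drag) in kg/s, ``f`` in pN; returns
    seconds.  Orders of magnitude below the ~5 s endocytic event time,
    which justifies treating every stage as a static equilibrium.
    """
    if f == 0:
        raise ZeroDivisionError("force must be nonzero")
    # nm * (kg/s) / pN = 1e-9 m * kg/s / 1e-12 N = 1e3 * m kg / (N s) = 1e3 s
    return L * eta_m / f * 1e3


def coat_adhesion_force(omega: float, R: float) -> float:
    """Pulling force pi*omega*R available from coat–membrane adhesion.

    ``omega`` in pN/nm (1e-3 N/m = 1 pN/nm), ``R`` in nm.  For realistic
    adhesion energies this is tens of pN, far below the ~1000-5000 pN
    force scale f_Pi set by turgor: adhesion alone cannot drive
    invagination in walled cells.
    """
    return math.pi * omega * R
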