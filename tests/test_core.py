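"""Closed-form scales, energy quadrature and analytic limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turgorshape import (
    ModelParams,
    ShapeProfile,
    coat_adhesion_force,
    derived_scales,
    evaluate_energy,
    geometric_observables,
    initiation_force,
    quasistatic_timescale,
    tube_limit,
)
from turgorshape.core import InvalidParamsError, ResolutionError


# ---------------------------------------------------------------------------
# derived scales
# ---------------------------------------------------------------------------

def test_scales_at_table_values():
    # bare bilayer rigidity 40 kBT = 160 pN nm under 1 MPa turgor
    p = ModelParams(kappa=160.0, sigma=1.0, Pi=1.0)
    d = derived_scales(p)
    assert d.R_Pi == pytest.approx(80.0 ** (1 / 3), rel=1e-12)  # ~4.31 nm
    assert d.lam == pytest.approx(math.sqrt(80.0), rel=1e-12)  # ~8.94 nm
    # fitted-scale force: R_Pi = 20 nm at 1 MPa
    p2 = ModelParams(kappa=2 * 1.0 * 20.0**3, Pi=1.0)
    assert derived_scales(p2).f_Pi == pytest.approx(4 * math.pi * 400.0, rel=1e-12)


def test_zero_tension_gives_infinite_tension_length():
    assert derived_scales(ModelParams(kappa=100.0, Pi=0.5)).lam == math.inf


@settings(max_examples=50, deadline=None, derandomize=True)
@given(kappa=st.floats(1.0, 1e5), Pi=st.floats(1e-3, 10.0))
def test_force_scale_identity(kappa, Pi):
    # 2 pi kappa / R_Pi and 4 pi Pi R_Pi^2 are the same number
    p = ModelParams(kappa=kappa, Pi=Pi)
    d = derived_scales(p)
    assert 2 * math.pi * kappa / d.R_Pi == pytest.approx(d.f_Pi, rel=1e-12)


@pytest.mark.parametrize("bad", [
    dict(kappa=-1.0, Pi=1.0),
    dict(kappa=0.0, Pi=1.0),
    dict(kappa=1.0, Pi=-0.2),
    dict(kappa=1.0, Pi=1.0, sigma=-1e-3),
    dict(kappa=1.0, Pi=1.0, Gamma=1.0, R0=0.0),
])
def test_invalid_parameters_rejected(bad):
    with pytest.raises(InvalidParamsError):
        ModelParams(**bad)


# ---------------------------------------------------------------------------
# energy evaluation on analytic surfaces
# ---------------------------------------------------------------------------

def sphere_profile(R=1.0, n=2000, frac=1.0):
    """Sphere of radius R sitting on the wall, traversed pole to pole."""
    th = np.linspace(1e-6, frac * math.pi, n)
    return ShapeProfile(s=R * th, r=R * np.sin(th),
                        z=R * (1 + np.cos(th)), psi=th)


def cap_profile(R=2.0, h=0.8, n=1500):
    th_max = math.acos(1 - h / R)
    th = np.linspace(1e-6, th_max, n)
    return ShapeProfile(s=R * th, r=R * np.sin(th),
                        z=R * (np.cos(th) - math.cos(th_max)), psi=th)


def cylinder_profile(R=1.0, ell=5.0, n=1500):
    s = np.linspace(0.0, ell, n)
    return ShapeProfile(s=s, r=np.full(n, R), z=ell - s,
                        psi=np.full(n, math.pi / 2))


@pytest.mark.parametrize("R", [0.5, 1.0, 3.7])
def test_sphere_bending_energy_scale_free(R):
    p = ModelParams(kappa=1.0, Pi=1e-9)
    prof = sphere_profile(R)
    e = evaluate_energy(prof, p)
    assert e.E_bend == pytest.approx(8 * math.pi, rel=2e-3)


def test_sphere_matching_spontaneous_curvature_costs_nothing():
    R = 1.5
    p = ModelParams(kappa=1.0, Pi=1e-9, C0=2.0 / R)
    assert evaluate_energy(sphere_profile(R), p).E_bend == pytest.approx(0.0, abs=1e-4)


def test_cylinder_energy_at_natural_radius():
    # per unit length: pi kappa / R + Pi pi R^2 = (3/2) pi kappa / R_Pi at R = R_Pi
    p = ModelParams(kappa=1.0, Pi=0.5)  # R_Pi = 1
    ell = 5.0
    e = evaluate_energy(cylinder_profile(R=1.0, ell=ell), p)
    assert e.E_bend + e.E_pressure == pytest.approx(1.5 * math.pi * ell, rel=1e-3)


def test_bar_energy_vanishes_on_preferred_cylinder():
    p = ModelParams(kappa=1.0, Pi=0.5, Gamma=2.0, R0=1.0)
    e = evaluate_energy(cylinder_profile(R=1.0, ell=4.0), p)
    assert e.E_bar == pytest.approx(0.0, abs=1e-9)
    p2 = ModelParams(kappa=1.0, Pi=0.5, Gamma=2.0, R0=0.5)
    assert evaluate_energy(cylinder_profile(R=1.0, ell=4.0), p2).E_bar > 0.1


def test_spherical_cap_volume_and_area():
    R, h = 2.0, 0.8
    obs = geometric_observables(cap_profile(R, h))
    assert obs.V == pytest.approx(math.pi * h**2 * (R - h / 3), rel=1e-3)
    assert obs.S == pytest.approx(2 * math.pi * R * h, rel=1e-3)
    assert obs.tip_radius == pytest.approx(R, rel=0.05)


def test_energy_breakdown_totals_are_consistent():
    p = ModelParams(kappa=1.0, Pi=0.5, sigma=0.03, C0=0.2)
    e = evaluate_energy(cap_profile(), p, f_a=2.0)
    assert e.F_total == pytest.approx(e.E_deform + e.work, rel=1e-12)
    assert e.E_deform == pytest.approx(
        e.E_bend + e.E_tension + e.E_pressure + e.E_bar, rel=1e-12)
    assert min(e.E_bend, e.E_tension, e.E_pressure, e.E_bar) >= 0.0


def test_quadrature_error_shrinks_under_refinement():
    p = ModelParams(kappa=1.0, Pi=1e-9)
    errs = [abs(evaluate_energy(sphere_profile(1.0, n=n), p).E_bend - 8 * math.pi)
            for n in (200, 800, 3200)]
    assert errs[2] < errs[1] < errs[0]


def test_too_coarse_profile_is_rejected():
    p = ModelParams(kappa=1.0, Pi=0.5)
    with pytest.raises(ResolutionError):
        evaluate_energy(sphere_profile(n=8), p, min_nodes=32)


def test_profile_geometric_consistency():
    prof = sphere_profile(1.0, n=4000)
    assert prof.geometric_residual() < 5e-3


# ---------------------------------------------------------------------------
# analytic force limits
# ---------------------------------------------------------------------------

def test_initiation_force_flat_membrane():
    p = ModelParams(kappa=1.0, Pi=0.5, C0=0.4)  # R_Pi = 1, f_Pi = 2 pi
    assert initiation_force(p) == pytest.approx(4 * math.pi * 0.4, rel=1e-12)
    assert initiation_force(p) / p.f_Pi == pytest.approx(0.8, rel=1e-12)
    assert initiation_force(ModelParams(kappa=1.0, Pi=0.5)) == 0.0


def test_tube_limit_closed_form():
    # C0 = sigma = 0: radius R_Pi, force (3/4) f_Pi exactly
    p = ModelParams(kappa=1.0, Pi=0.5)
    R, f = tube_limit(p)
    assert R == pytest.approx(1.0, rel=1e-6)
    assert f / p.f_Pi == pytest.approx(0.75, rel=1e-6)


def test_tube_limit_with_spontaneous_curvature():
    # 1-D minimization oracle: e(R) = pi (1/R - C0)^2 R + pi R^2 / 2
    p = ModelParams(kappa=1.0, Pi=0.5, C0=0.4)
    R, f = tube_limit(p)
    grid = np.linspace(0.2, 3.0, 20001)
    e = math.pi * (1 / grid - 0.4) ** 2 * grid + 0.5 * math.pi * grid**2
    assert R == pytest.approx(grid[e.argmin()], abs=2e-4)
    assert f == pytest.approx(e.min(), rel=1e-8)
    assert R == pytest.approx(0.948, abs=2e-3)
    assert f / p.f_Pi == pytest.approx(0.43, abs=5e-3)


def test_tube_force_increases_with_tension():
    forces = [tube_limit(ModelParams(kappa=1.0, Pi=0.5, sigma=s))[1]
              for s in (0.0, 0.05, 0.1, 0.2)]
    assert np.all(np.diff(forces) > 0)


def test_quasistatic_timescale():
    # 100 nm at 300 pN with membrane drag 1e-8 kg/s: microseconds
    t = quasistatic_timescale(100.0, 1e-8, 300.0)
    assert t == pytest.approx(3.33e-6, rel=1e-2)
    assert quasistatic_timescale(0.0, 1e-8, 300.0) == 0.0
    assert quasistatic_timescale(100.0, 1e-8, 600.0) == pytest.approx(t / 2)
    with pytest.raises(ZeroDivisionError):
        quasistatic_timescale(100.0, 1e-8, 0.0)


def test_coat_adhesion_force_is_tens_of_pN():
    assert coat_adhesion_force(1.0, 10.0) == pytest.approx(31.4, abs=0.1)
    assert coat_adhesion_force(0.1, 10.0) == pytest.approx(3.14, abs=0.01)
    assert coat_adhesion_force(0.0, 10.0) == 0.0
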