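"""Boundary-value solver: oracle equivalence, limits and invariants."""

import math

import numpy as np
import pytest

from turgorshape import (
    ModelParams,
    NoEquilibriumError,
    RigidityProfile,
    direct_minimization_oracle,
    evaluate_energy,
    initiation_force,
    solve_heterogeneous,
    solve_shape,
    tube_limit,
)
from tests.conftest import curve_distance, nd_params


def test_long_invagination_reaches_tube_limit():
    p = nd_params()
    sol = solve_shape(p, L=8.0)
    _, f_tube = tube_limit(p)
    assert sol.f_a == pytest.approx(f_tube, rel=0.03)


@pytest.mark.parametrize("C0,sigma,L", [
    (0.4, 0.0, 2.0),
    (0.2, 0.05, 0.5),
])
def test_bvp_matches_direct_minimization(C0, sigma, L):
    """Spot checks of the full oracle-equivalence grid (see acceptance)."""
    p = nd_params(C0=C0, sigma=sigma)
    bvp = solve_shape(p, L=L)
    orc = direct_minimization_oracle(p, L, n_nodes=120, compute_force=False)
    assert abs(orc.energy - bvp.energies.E_deform) / bvp.energies.E_deform < 0.01
    assert curve_distance(orc.profile, bvp.profile) < 0.02


def test_bvp_matches_oracle_with_bar_term():
    p = nd_params(C0=1.0, Gamma=1.0, R0=1.0)
    bvp = solve_shape(p, L=1.2)
    orc = direct_minimization_oracle(p, 1.2, n_nodes=120, compute_force=True, dL=0.03)
    assert abs(orc.energy - bvp.energies.E_deform) / bvp.energies.E_deform < 0.01
    assert bvp.f_a == pytest.approx(orc.f_a, rel=0.03)


@pytest.mark.parametrize("C0,sigma", [(0.4, 0.0), (0.4, 0.05), (0.0, 0.1)])
def test_initiation_force_is_small_height_limit(C0, sigma):
    """f_a(L->0) extrapolates to 4 pi kappa sqrt(C0^2 + 2 sigma/kappa)."""
    p = nd_params(C0=C0, sigma=sigma)
    Ls = np.array([0.05, 0.035, 0.02])
    fs = []
    warm = None
    for L in Ls:
        sol = solve_shape(p, L=L, warm_start=warm)
        warm = sol
        fs.append(sol.f_a)
    # linear extrapolation to L = 0
    coef = np.polyfit(Ls, fs, 1)
    f0_num = coef[1]
    assert f0_num == pytest.approx(initiation_force(p), rel=0.02)


def test_force_target_and_height_target_agree():
    p = nd_params(C0=0.2)
    a = solve_shape(p, L=1.5)
    b = solve_shape(p, f_a=a.f_a, warm_start=a)
    assert b.observables.L == pytest.approx(1.5, rel=5e-3)


def test_force_is_nondecreasing_in_tension():
    p_list = [nd_params(C0=0.2, sigma=s) for s in (0.0, 0.05, 0.15)]
    fs = [solve_shape(p, L=2.0).f_a for p in p_list]
    assert fs[0] < fs[1] < fs[2]


def test_solutions_scale_invariant_under_kappa_Pi_rescaling():
    base = nd_params(C0=0.3, sigma=0.02)
    ref = solve_shape(base, L=2.0)
    for c in (0.2, 5.0):
        p = base.rescaled(c)
        assert p.R_Pi == pytest.approx(base.R_Pi, rel=1e-12)
        sol = solve_shape(p, L=2.0, warm_start=ref)
        assert sol.f_a / p.f_Pi == pytest.approx(ref.f_a / base.f_Pi, rel=1e-4)
        assert curve_distance(sol.profile, ref.profile) < 1e-3


def test_stored_energies_match_reevaluation():
    p = nd_params(C0=0.4)
    sol = solve_shape(p, L=2.0)
    e = evaluate_energy(sol.profile, p, f_a=sol.f_a)
    assert e.E_deform == pytest.approx(sol.energies.E_deform, rel=1e-9)
    assert sol.profile.geometric_residual() < 1e-2
    assert sol.converged and sol.residual < 1e-5


def test_no_equilibrium_inside_gap():
    # strong curvature: a range of heights has no equilibrium shape
    p = nd_params(C0=1.0)
    with pytest.raises(NoEquilibriumError):
        solve_shape(p, L=1.8)


def test_gamma_zero_matches_bar_free_input():
    pa = nd_params(C0=0.3)
    pb = nd_params(C0=0.3, Gamma=0.0, R0=2.0)
    a = solve_shape(pa, L=1.5)
    b = solve_shape(pb, L=1.5)
    assert a.f_a == pytest.approx(b.f_a, rel=1e-10)


# ---------------------------------------------------------------------------
# heterogeneous rigidity
# ---------------------------------------------------------------------------

def test_uniform_rigidity_profile_reduces_to_homogeneous():
    p = nd_params()
    rig = RigidityProfile(kappa_tip=p.kappa, kappa_min=p.kappa, A_tip=2.0, w=0.3)
    het = solve_heterogeneous(p, rig, L=2.0)
    hom = solve_shape(p, L=2.0)
    assert het.f_a == hom.f_a  # same code path, bitwise


def test_soft_base_lowers_force_then_destabilizes():
    p = nd_params()
    hom = solve_shape(p, L=2.0)
    soft = solve_heterogeneous(
        p, RigidityProfile(p.kappa, 0.5 * p.kappa, A_tip=2.0, w=0.3), L=2.0)
    assert soft.f_a < hom.f_a
    with pytest.raises(NoEquilibriumError):
        solve_heterogeneous(
            p, RigidityProfile(p.kappa, 0.05 * p.kappa, A_tip=2.0, w=0.3), L=2.0)


def test_rigidity_instability_threshold_shifts_with_stiff_area():
    """A larger stiff tip cap tolerates a softer base."""
    p = nd_params()

    def stable(ratio, A_tip):
        try:
            solve_heterogeneous(
                p, RigidityProfile(p.kappa, ratio * p.kappa, A_tip=A_tip, w=0.3),
                L=2.0)
            return True
        except NoEquilibriumError:
            return False

    def threshold(A_tip, lo=0.02, hi=1.0):
        for _ in range(5):
            mid = 0.5 * (lo + hi)
            if stable(mid, A_tip):
                hi = mid
            else:
                lo = mid
        return hi

    t_small, t_large = threshold(1.0), threshold(6.0)
    assert t_large <= t_small


def test_rigidity_profile_validation():
    with pytest.raises(ValueError):
        RigidityProfile(kappa_tip=1.0, kappa_min=2.0, A_tip=1.0, w=0.1)
    with pytest.raises(ValueError):
        RigidityProfile(kappa_tip=1.0, kappa_min=0.5, A_tip=-1.0, w=0.1)
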