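"""Neck closure, critical curvature and scission by BAR removal."""

import numpy as np
import pytest

from turgorshape import (
    NECK_CLOSURE_EPS,
    NoEquilibriumError,
    critical_curvature_at_length,
    scission_test,
    solve_shape,
)
from tests.conftest import nd_params


def test_neck_shrinks_with_spontaneous_curvature_and_closes():
    """At fixed height the neck radius decreases in C0 up to closure."""
    L = 2.8
    necks = []
    warm = None
    for c0 in (0.0, 0.2, 0.3, 0.38, 0.44):
        sol = solve_shape(nd_params(C0=c0), L=L, warm_start=warm)
        warm = sol
        necks.append(sol.observables.neck_radius)
    assert np.all(np.diff(necks) < 0)
    assert necks[0] > 0.5  # no constriction without curvature

    c0_plus = critical_curvature_at_length(L, 0.0, tol_nd=2e-2)
    # closure at this height happens between the hysteresis worked example
    # (0.45, where a small-neck shape still exists) and the gap one (1.0)
    assert 0.45 < c0_plus < 1.0
    # slightly above the threshold no open-neck equilibrium exists
    with pytest.raises(NoEquilibriumError):
        solve_shape(nd_params(C0=c0_plus + 0.1), L=L, warm_start=warm,
                    fallback=False)


def test_bar_removal_triggers_scission():
    """Gamma -> 0 at fixed height collapses the neck (scission trigger)."""
    p = nd_params(C0=1.0, Gamma=1.0, R0=1.0)
    rep = scission_test(p, L=3.0, n_steps=8)
    assert rep["scission"]
    necks = [n for _, n in rep["gamma_neck"] if np.isfinite(n)]
    assert np.all(np.diff(necks) < 0)  # neck shrinks monotonically
    assert necks[0] > 5 * NECK_CLOSURE_EPS  # starts comfortably open


def test_bar_coat_allows_stable_necked_shape():
    """With the BAR term the strongly curved invagination holds a neck."""
    p = nd_params(C0=1.0, Gamma=1.0, R0=1.0)
    sol = solve_shape(p, L=3.0)
    assert sol.converged
    assert sol.observables.neck_radius > NECK_CLOSURE_EPS
    # without BAR rigidity the same height is inside the gap
    with pytest.raises(NoEquilibriumError):
        solve_shape(nd_params(C0=1.0), L=1.8)


@pytest.fixture(scope="module")
def hysteresis_report():
    from turgorshape import classify_regime

    return classify_regime(nd_params(C0=0.45), L_range=(0.0, 5.0),
                           dS0=0.22, max_points=200)


def test_energy_crossing_prefers_spheroid_at_lower_energy(hysteresis_report):
    """Across the hysteresis overlap the branch with lower deformation
    energy is preferred; the crossing lies inside the overlap."""
    from turgorshape import energy_crossing

    p = nd_params(C0=0.45)
    df = energy_crossing(p, report=hysteresis_report)
    lo, hi = hysteresis_report.interval
    assert lo <= df.attrs["L_cross_nm"] <= hi
    pref = df["preferred"]
    e_pref = np.where(pref == "spheroidal", df["E_spheroidal"], df["E_tubular"])
    e_other = np.where(pref == "spheroidal", df["E_tubular"], df["E_spheroidal"])
    assert np.all(e_pref <= e_other + 1e-9)
    # the two branches carry different forces at equal height (force loop)
    assert np.max(np.abs(df["fa_tubular"] - df["fa_spheroidal"])) > 1e-2


def test_tubular_to_spheroid_transition_trades_bending_for_pressure(hysteresis_report):
    """At equal height the spheroidal shape has lower bending energy and
    higher pressure energy than the tubular one."""
    from turgorshape import branch_energy_components

    p = nd_params(C0=0.45)
    lo, hi = hysteresis_report.interval
    mid = 0.5 * (lo + hi)
    tub, sph = branch_energy_components(p, L=mid, curve=hysteresis_report.curve)
    assert sph.energies.E_bend < tub.energies.E_bend
    assert sph.energies.E_pressure > tub.energies.E_pressure
    # the spheroid is the compact, small-neck configuration
    assert sph.observables.neck_radius < tub.observables.neck_radius
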