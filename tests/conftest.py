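import numpy as np
import pytest
from scipy.spatial import cKDTree

from turgorshape import ModelParams, SolverOptions, trace_branch


def nd_params(C0=0.0, sigma=0.0, Gamma=0.0, R0=1.0, R_Pi=1.0, Pi=0.5):
    """Reduced-parameter model at unit width scale (R_Pi = 1 nm)."""
    return ModelParams.from_nd(C0_nd=C0, sigma_nd=sigma, Gamma_nd=Gamma,
                               R0_nd=R0, R_Pi=R_Pi, Pi=Pi)


def curve_distance(prof_a, prof_b, z_floor=0.02):
    """Max closest-point distance from a's lifted samples to b's curve."""
    m = prof_a.z > z_floor
    tree = cKDTree(np.column_stack([prof_b.r, prof_b.z]))
    d, _ = tree.query(np.column_stack([prof_a.r[m], prof_a.z[m]]))
    return float(d.max())


@pytest.fixture(scope="session")
def fitted_curve():
    """Force-length curve at the fitted spontaneous curvature C0 = 0.4/R_Pi."""
    return trace_branch(nd_params(C0=0.4), L_range=(0.0, 6.0))


@pytest.fixture(scope="session")
def bare_curve():
    """Force-length curve of the bare membrane (C0 = sigma = 0)."""
    return trace_branch(nd_params(), L_range=(0.0, 8.5))
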