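"""File formats and run configuration.

Everything is plain text: profiles and force-length curves as CSV,
parameters, solutions and reports as JSON.  Every written artifact embeds
the resolved configuration, package version and seed, so a run can be
reproduced from its own outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .core import ModelParams, ShapeProfile
from .solver import ForceLengthCurve, ShapeSolution

__all__ = [
    "params_to_json", "params_from_json", "write_solution", "read_profile_csv",
    "write_profile_csv", "write_curve_csv", "write_json",
]

PARAM_KEYS = {
    "kappa_pN_nm": "kappa",
    "sigma_pN_per_nm": "sigma",
    "Pi_pN_per_nm2": "Pi",
    "C0_per_nm": "C0",
    "Gamma_pN_nm": "Gamma",
    "R0_nm": "R0",
}


def params_to_json(params: ModelParams) -> dict:
    return {k: getattr(params, v) for k, v in PARAM_KEYS.items()}


def params_from_json(d: dict) -> ModelParams:
    missing = [k for k in ("kappa_pN_nm", "Pi_pN_per_nm2") if k not in d]
    if missing:
        raise KeyError(f"missing required parameter keys: {missing}")
    kwargs = {v: d[k] for k, v in PARAM_KEYS.items() if k in d}
    return ModelParams(**kwargs)


def _meta(seed=None, config=None) -> dict:
    out = {"package": "turgorshape", "version": _version}
    if seed is not None:
        out["seed"] = seed
    if config is not None:
        out["config"] = config
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, float) and math.isinf(o):
            return "inf"
        return super().default(o)


def write_json(path, obj: dict, seed=None, config=None) -> None:
    payload = dict(obj)
    payload["_meta"] = _meta(seed=seed, config=config)
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder))


def write_profile_csv(path, profile: ShapeProfile) -> None:
    pd.DataFrame({
        "s_nm": profile.s, "r_nm": profile.r,
        "z_nm": profile.z, "psi_rad": profile.psi,
    }).to_csv(path, index=False)


def read_profile_csv(path) -> ShapeProfile:
    df = pd.read_csv(path)
    return ShapeProfile(s=df["s_nm"].to_numpy(), r=df["r_nm"].to_numpy(),
                        z=df["z_nm"].to_numpy(), psi=df["psi_rad"].to_numpy())


def write_solution(prefix, sol: ShapeSolution, seed=None, config=None) -> None:
    """ShapeSolution -> <prefix>.json (scalars) + <prefix>_profile.csv."""
    prefix = Path(prefix)
    write_profile_csv(prefix.parent / f"{prefix.name}_profile.csv", sol.profile)
    write_json(prefix.parent / f"{prefix.name}.json", {
        "params": params_to_json(sol.params),
        "f_a_pN": sol.f_a,
        "L_nm": sol.observables.L,
        "observables": dataclasses.asdict(sol.observables),
        "energies": dataclasses.asdict(sol.energies) | {
            "E_deform": sol.energies.E_deform, "F_total": sol.energies.F_total},
        "residual": sol.residual,
        "converged": sol.converged,
    }, seed=seed, config=config)


def write_curve_csv(path, curve: ForceLengthCurve) -> None:
    curve.to_frame().to_csv(path, index=False)
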