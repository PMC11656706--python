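r"""State equations of the GUTS variants.

The full model couples four states:

.. math::

    dC_i/dt &= k_i C_e - k_m P^* C_i \\
    dR/dt   &= r_{rt}\,a(C_i/C_{i,max}) - k_{rd}\max(0, R - R_0) \\
    dP^*/dt &= k_p (R - P^*) \\
    dH/dt   &= k_k \max(0, R - z) + h_b

with survival :math:`S = e^{-H}` under the stochastic-death assumption.
The activation :math:`a` is a logistic sigmoid in the scaled internal
concentration; any sigmoid mapping to (0, 1) is admissible and the logistic
form is the package default (configurable via ``activation_fn`` hooks where
exposed).  There is no passive elimination term: removal of the chemical is
exclusively protein-mediated.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .params import RnaPulseParams, ScalingContext, get_variant

__all__ = [
    "activation",
    "hazard",
    "survival_from_cumulative_hazard",
    "rhs_rna_pulse",
    "rhs_variant",
    "initial_state",
]


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"argument {name!r} contains non-finite values")
    return arr


def activation(c_scaled, z_ci: float, v_rt: float):
    """Logistic activation of *nrf2* expression on the scaled concentration.

    Returns ``1 / (1 + exp(-v_rt * (c_scaled - z_ci)))``: 0.5 exactly at the
    threshold, approaching a step function as ``v_rt`` grows.
    """
    c = _check_finite("c_scaled", c_scaled)
    z = _check_finite("z_ci", z_ci)
    v = _check_finite("v_rt", v_rt)
    if np.any(c < 0):
        raise ValueError("argument 'c_scaled' must be >= 0")
    if np.any(v <= 0):
        raise ValueError("argument 'v_rt' must be > 0")
    x = np.clip(v * (c - z), -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(-x))
    if np.isscalar(c_scaled) or np.ndim(c_scaled) == 0:
        return float(out)
    return out


def hazard(damage_level, z: float, k_k: float, h_b: float):
    """Threshold-linear hazard rate: ``k_k * max(0, damage - z) + h_b``."""
    d = _check_finite("damage_level", damage_level)
    for name, v in (("z", z), ("k_k", k_k), ("h_b", h_b)):
        _check_finite(name, v)
    if k_k < 0 or h_b < 0:
        raise ValueError("k_k and h_b must be >= 0")
    out = k_k * np.maximum(0.0, d - z) + h_b
    if np.ndim(damage_level) == 0:
        return float(out)
    return out


def survival_from_cumulative_hazard(H):
    """Map cumulative hazard to survival probability, ``S = exp(-H)``."""
    arr = _check_finite("H", H)
    if np.any(arr < 0):
        raise ValueError("cumulative hazard H must be >= 0")
    out = np.exp(-arr)
    if np.ndim(H) == 0:
        return float(out)
    return out


def _as_param_dict(params) -> Mapping[str, float]:
    if isinstance(params, RnaPulseParams):
        return params.to_dict()
    return params


def rhs_rna_pulse(state, t: float, params, scaling: ScalingContext, C_e: float):
    """Time-derivatives of the GUTS-RNA-pulse state ``(C_i, R, P_star, H)``.

    ``state`` may be a :class:`~gutspulse.params.ModelState` or an array of
    shape ``(4,)`` / ``(n, 4)``.
    """
    p = _as_param_dict(params)
    if hasattr(state, "as_array"):
        state = state.as_array()
    y = _check_finite("state", state)
    C_e = float(C_e)
    if not np.isfinite(C_e) or C_e < 0:
        raise ValueError(f"external concentration C_e must be finite and >= 0, got {C_e}")
    if scaling.C_i_max <= 0:
        raise ValueError("scaling.C_i_max must be > 0")
    C_i = y[..., 0]
    R = y[..., 1]
    P = y[..., 2]
    a = activation(np.maximum(C_i, 0.0) / scaling.C_i_max, p["z_ci"], p["v_rt"])
    dC_i = p["k_i"] * C_e - p["k_m"] * P * C_i
    dR = p["r_rt"] * a - p["k_rd"] * np.maximum(0.0, R - scaling.R_0)
    dP = p["k_p"] * (R - P)
    dH = hazard(R, p["z"], p["k_k"], p["h_b"])
    return np.stack(
        [np.broadcast_to(dC_i, np.shape(C_i)), np.asarray(dR), np.asarray(dP), np.asarray(dH)],
        axis=-1,
    ) if y.ndim > 1 else np.array([dC_i, dR, dP, dH], dtype=float)


def rhs_variant(
    variant: str,
    state,
    t: float,
    params,
    C_e: float,
    scaling: ScalingContext | None = None,
):
    """Dispatch the right-hand side of any registered variant.

    The comparison variants are standard one-compartment GUTS-SD forms;
    ``guts_rna`` uses the *nrf2* fold-change itself as the damage state
    (baseline ``D_0 = R_0 = 1``).
    """
    spec = get_variant(variant)
    if variant == "guts_rna_pulse":
        if scaling is None:
            raise ValueError("guts_rna_pulse requires a ScalingContext")
        return rhs_rna_pulse(state, t, params, scaling, C_e)
    p = _as_param_dict(params)
    y = _check_finite("state", state)
    C_e = float(C_e)
    if not np.isfinite(C_e) or C_e < 0:
        raise ValueError(f"external concentration C_e must be finite and >= 0, got {C_e}")
    if variant == "guts_reduced":
        D = y[..., 0]
        dD = p["k_d"] * (C_e - D)
        dH = hazard(D, p["z"], p["k_k"], p["h_b"])
        return np.array([dD, dH], dtype=float)
    if variant == "guts_scaled_damage":
        C_i, D = y[..., 0], y[..., 1]
        dC = p["k_i"] * C_e - p["k_e"] * C_i
        dD = p["k_d"] * (C_i - D)
        dH = hazard(D, p["z"], p["k_k"], p["h_b"])
        return np.array([dC, dD, dH], dtype=float)
    if variant == "guts_rna":
        D0 = 1.0 if scaling is None else scaling.R_0
        C_i, D = y[..., 0], y[..., 1]
        dC = p["k_i"] * C_e - p["k_e"] * C_i
        dD = p["k_a"] * C_i - p["k_r"] * (D - D0)
        dH = hazard(D, p["z"], p["k_k"], p["h_b"])
        return np.array([dC, dD, dH], dtype=float)
    raise ValueError(f"unknown variant {spec.name!r}")  # pragma: no cover


def initial_state(variant: str, scaling: ScalingContext | None = None) -> np.ndarray:
    """Untreated baseline equilibrium at exposure start (t = 0 hpe)."""
    r0 = 1.0 if scaling is None else scaling.R_0
    if variant == "guts_reduced":
        return np.array([0.0, 0.0])
    if variant in ("guts_scaled_damage",):
        return np.array([0.0, 0.0, 0.0])
    if variant == "guts_rna":
        return np.array([0.0, r0, 0.0])
    if variant == "guts_rna_pulse":
        return np.array([0.0, r0, r0, 0.0])
    get_variant(variant)
    raise AssertionError  # pragma: no cover
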