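"""Jitted fixed-step RK4 integrators for batched likelihood evaluation.

One parameter vector, many treatments of one substance with constant
external concentration each: the per-treatment systems are independent, so
they are integrated in one compiled loop.  The step size is bounded by the
fastest first-order rate in the parameter set (RK4 stability), and runs that
would need an unreasonable number of steps or that overflow return NaNs,
which the likelihood treats as an infeasible parameter region.

The high-accuracy adaptive path lives in :mod:`gutspulse.simulate`; a test
cross-checks the two.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_STATE_CAP = 1e12
_MAX_STEPS = 400_000


@njit(cache=True)
def _integrate_rna_pulse(ce, p, cimax, r0, t_out, h):
    # p = (k_i, k_m, z_ci, v_rt, r_rt, k_rd, k_p, z, k_k, h_b)
    n = ce.shape[0]
    nt = t_out.shape[0]
    out = np.empty((n, 4, nt))
    k_i, k_m, z_ci, v_rt = p[0], p[1], p[2], p[3]
    r_rt, k_rd, k_p, z, k_k, h_b = p[4], p[5], p[6], p[7], p[8], p[9]
    for j in range(n):
        c = 0.0
        r = r0
        pr = r0
        H = 0.0
        t = 0.0
        ok = True
        for m in range(nt):
            tt = t_out[m]
            if ok and tt > t:
                nstep = int(np.ceil((tt - t) / h))
                if nstep < 1:
                    nstep = 1
                dt = (tt - t) / nstep
                for _ in range(nstep):
                    # RK4 on (c, r, pr, H)
                    c1, r1, p1, H1 = c, r, pr, H
                    dc1, dr1, dp1, dH1 = _rhs_pulse(
                        c1, r1, p1, ce[j], k_i, k_m, z_ci, v_rt, r_rt, k_rd,
                        k_p, z, k_k, h_b, cimax, r0)
                    c2 = c + 0.5 * dt * dc1
                    r2 = r + 0.5 * dt * dr1
                    p2 = pr + 0.5 * dt * dp1
                    dc2, dr2, dp2, dH2 = _rhs_pulse(
                        c2, r2, p2, ce[j], k_i, k_m, z_ci, v_rt, r_rt, k_rd,
                        k_p, z, k_k, h_b, cimax, r0)
                    c3 = c + 0.5 * dt * dc2
                    r3 = r + 0.5 * dt * dr2
                    p3 = pr + 0.5 * dt * dp2
                    dc3, dr3, dp3, dH3 = _rhs_pulse(
                        c3, r3, p3, ce[j], k_i, k_m, z_ci, v_rt, r_rt, k_rd,
                        k_p, z, k_k, h_b, cimax, r0)
                    c4 = c + dt * dc3
                    r4 = r + dt * dr3
                    p4 = pr + dt * dp3
                    dc4, dr4, dp4, dH4 = _rhs_pulse(
                        c4, r4, p4, ce[j], k_i, k_m, z_ci, v_rt, r_rt, k_rd,
                        k_p, z, k_k, h_b, cimax, r0)
                    c = c + dt * (dc1 + 2 * dc2 + 2 * dc3 + dc4) / 6.0
                    r = r + dt * (dr1 + 2 * dr2 + 2 * dr3 + dr4) / 6.0
                    pr = pr + dt * (dp1 + 2 * dp2 + 2 * dp3 + dp4) / 6.0
                    H = H + dt * (dH1 + 2 * dH2 + 2 * dH3 + dH4) / 6.0
                    if c < 0.0:
                        c = 0.0
                    if not (np.isfinite(c) and np.isfinite(r)
                            and np.isfinite(pr) and np.isfinite(H)):
                        ok = False
                        break
                    if c > _STATE_CAP or r > _STATE_CAP or H > _STATE_CAP:
                        ok = False
                        break
                t = tt
            if ok:
                out[j, 0, m] = c
                out[j, 1, m] = r
                out[j, 2, m] = pr
                out[j, 3, m] = H
            else:
                out[j, 0, m] = np.nan
                out[j, 1, m] = np.nan
                out[j, 2, m] = np.nan
                out[j, 3, m] = np.nan
    return out


@njit(cache=True, inline="always")
def _rhs_pulse(c, r, pr, ce, k_i, k_m, z_ci, v_rt, r_rt, k_rd, k_p, z, k_k,
               h_b, cimax, r0):
    cs = c / cimax
    if cs < 0.0:
        cs = 0.0
    x = v_rt * (cs - z_ci)
    if x > 50.0:
        a = 1.0
    elif x < -50.0:
        a = 0.0
    else:
        a = 1.0 / (1.0 + np.exp(-x))
    dc = k_i * ce - k_m * pr * c
    excess = r - r0
    if excess < 0.0:
        excess = 0.0
    dr = r_rt * a - k_rd * excess
    dp = k_p * (r - pr)
    over = r - z
    if over < 0.0:
        over = 0.0
    dH = k_k * over + h_b
    return dc, dr, dp, dH


@njit(cache=True)
def _integrate_linear3(ce, p, d0, t_out, h, mode):
    """Shared RK4 loop for the linear comparison variants.

    mode 0: guts_reduced      states (D, H),       p = (k_d, z, k_k, h_b)
    mode 1: guts_scaled_damage states (C_i, D, H), p = (k_i, k_e, k_d, z, k_k, h_b)
    mode 2: guts_rna           states (C_i, D, H), p = (k_i, k_e, k_a, k_r, z, k_k, h_b)
    """
    n = ce.shape[0]
    nt = t_out.shape[0]
    out = np.empty((n, 3, nt))
    for j in range(n):
        c = 0.0
        d = d0 if mode == 2 else 0.0
        H = 0.0
        t = 0.0
        ok = True
        for m in range(nt):
            tt = t_out[m]
            if ok and tt > t:
                nstep = int(np.ceil((tt - t) / h))
                if nstep < 1:
                    nstep = 1
                dt = (tt - t) / nstep
                for _ in range(nstep):
                    y0 = (c, d, H)
                    k1 = _rhs_lin(y0[0], y0[1], ce[j], p, d0, mode)
                    y1 = (c + 0.5 * dt * k1[0], d + 0.5 * dt * k1[1], 0.0)
                    k2 = _rhs_lin(y1[0], y1[1], ce[j], p, d0, mode)
                    y2 = (c + 0.5 * dt * k2[0], d + 0.5 * dt * k2[1], 0.0)
                    k3 = _rhs_lin(y2[0], y2[1], ce[j], p, d0, mode)
                    y3 = (c + dt * k3[0], d + dt * k3[1], 0.0)
                    k4 = _rhs_lin(y3[0], y3[1], ce[j], p, d0, mode)
                    c = c + dt * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
                    d = d + dt * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
                    H = H + dt * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
                    if not (np.isfinite(c) and np.isfinite(d) and np.isfinite(H)):
                        ok = False
                        break
                t = tt
            if ok:
                out[j, 0, m] = c
                out[j, 1, m] = d
                out[j, 2, m] = H
            else:
                out[j, 0, m] = np.nan
                out[j, 1, m] = np.nan
                out[j, 2, m] = np.nan
    return out


@njit(cache=True, inline="always")
def _rhs_lin(c, d, ce, p, d0, mode):
    if mode == 0:
        k_d, z, k_k, h_b = p[0], p[1], p[2], p[3]
        dd = k_d * (ce - d)
        dc = 0.0
    elif mode == 1:
        k_i, k_e, k_d, z, k_k, h_b = p[0], p[1], p[2], p[3], p[4], p[5]
        dc = k_i * ce - k_e * c
        dd = k_d * (c - d)
    else:
        k_i, k_e, k_a, k_r, z, k_k, h_b = (
            p[0], p[1], p[2], p[3], p[4], p[5], p[6])
        dc = k_i * ce - k_e * c
        dd = k_a * c - k_r * (d - d0)
    over = d - z
    if over < 0.0:
        over = 0.0
    dH = k_k * over + h_b
    return dc, dd, dH


def _stable_step(variant: str, p: dict, r0: float, t_end: float, h: float) -> float:
    """Bound the RK4 step by the fastest linear rate in the system."""
    if variant == "guts_rna_pulse":
        r_max = r0 + min(p["r_rt"] / max(p["k_rd"], 1e-12), p["r_rt"] * t_end)
        rate = max(p["k_rd"], p["k_p"], p["k_m"] * r_max, 1e-9)
    elif variant == "guts_reduced":
        rate = max(p["k_d"], 1e-9)
    elif variant == "guts_scaled_damage":
        rate = max(p["k_e"], p["k_d"], 1e-9)
    else:
        rate = max(p["k_e"], p["k_r"], 1e-9)
    return min(h, 1.0 / rate)


def fast_solve(variant, params, ce_values, t_out, scaling=None, h=0.05):
    """Integrate ``variant`` for many constant-exposure treatments at once.

    Parameters
    ----------
    params : mapping of natural-scale parameter values
    ce_values : array (n,) of constant external concentrations
    t_out : sorted array of output times (model clock, hpe)

    Returns
    -------
    array of shape (n_treatments, n_states, n_times); NaN-filled rows signal
    an infeasible/unstable parameter region.
    """
    ce = np.ascontiguousarray(ce_values, dtype=float)
    t = np.ascontiguousarray(t_out, dtype=float)
    t_end = float(t[-1]) if len(t) else 0.0
    r0 = 1.0 if scaling is None else float(scaling.R_0)
    h_eff = _stable_step(variant, params, r0, max(t_end, 1.0), h)
    if t_end > 0 and t_end / h_eff > _MAX_STEPS:
        n_states = {"guts_rna_pulse": 4, "guts_reduced": 2}.get(variant, 3)
        return np.full((len(ce), n_states, len(t)), np.nan)
    if variant == "guts_rna_pulse":
        cimax = float(scaling.C_i_max)
        pv = np.array(
            [params[k] for k in (
                "k_i", "k_m", "z_ci", "v_rt", "r_rt", "k_rd", "k_p", "z",
                "k_k", "h_b")],
            dtype=float,
        )
        return _integrate_rna_pulse(ce, pv, cimax, r0, t, h_eff)
    if variant == "guts_reduced":
        pv = np.array([params[k] for k in ("k_d", "z", "k_k", "h_b")])
        # drop the unused first row so the layout matches the registry (D, H)
        return _integrate_linear3(ce, pv, 0.0, t, h_eff, 0)[:, 1:, :]
    if variant == "guts_scaled_damage":
        pv = np.array(
            [params[k] for k in ("k_i", "k_e", "k_d", "z", "k_k", "h_b")])
        return _integrate_linear3(ce, pv, 0.0, t, h_eff, 1)
    if variant == "guts_rna":
        pv = np.array(
            [params[k] for k in ("k_i", "k_e", "k_a", "k_r", "z", "k_k", "h_b")])
        return _integrate_linear3(ce, pv, r0, t, h_eff, 2)
    raise ValueError(f"unknown variant {variant!r}")
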