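"""Right-hand-side quantities of the sleep-wake switch model.

Pure functions evaluating every component of the coupled system

    tau_v dV_v/dt = nu_vm Q(V_m) + D_v - V_v            (+ noise)
    tau_m dV_m/dt = nu_mv Q(V_v) + D_m - V_m            (+ noise)
    tau_o dV_o/dt = nu_ov Q(V_v) + nu_om Q(V_m) + D_o - V_o
    chi  dH/dt    = mu (1 - exp(-Q(V_m)/q_sat)) - H

with net drives

    D_v = nu_vc C(t) + nu_vh H + a_v
    D_m = nu_mo Q(V_o) + a_m
    D_o = nu_oc C(t) + nu_oh H + a_o

and C(t) = cos(omega (t - phase_ref)).  All functions accept scalars or
numpy arrays in their state arguments.
"""

from __future__ import annotations

import numpy as np

from .params import (CouplingParams, DriveParams, HomeostatParams,
                     ModelParameters, SigmoidParams, SystemState)

__all__ = [
    "firing_rate", "circadian_drive", "net_drive_vlpo", "net_drive_ma",
    "net_drive_orx", "homeostat_production", "homeostat_rate", "rhs_full",
    "derived_quantities",
]


def firing_rate(v, p: SigmoidParams):
    """Mean population firing rate Q(V) (s^-1) for potential ``v`` (mV).

    Strictly increasing and bounded in (0, q_max).  Rejects non-finite
    input rather than silently saturating.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("firing_rate: non-finite potential")
    # evaluate in a form stable against overflow for very negative v
    x = (v - p.theta) / p.sigma_prime
    out = p.q_max * _expit(x)
    return out if out.ndim else float(out)


def _expit(x):
    out = np.empty_like(x, dtype=float) if np.ndim(x) else None
    pos = x >= 0
    if np.ndim(x):
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    if pos:
        return 1.0 / (1.0 + np.exp(-x))
    ex = np.exp(x)
    return ex / (1.0 + ex)


def circadian_drive(t, p: DriveParams):
    """Unit-amplitude 24-h sinusoidal circadian drive C(t).

    ``t`` is simulation time in seconds; t = 0 is clock midnight.  The
    maximum falls at clock time ``p.phase_ref`` each day.
    """
    t = np.asarray(t, dtype=float)
    out = np.cos(p.omega * (t - p.phase_ref))
    return out if out.ndim else float(out)


def net_drive_vlpo(c, h, p: DriveParams):
    """Net drive to the VLPO: D_v = nu_vc c + nu_vh h + a_v (mV)."""
    return p.nu_vc * np.asarray(c, float) + p.nu_vh * np.asarray(h, float) + p.a_v


def net_drive_ma(q_o, coupling: CouplingParams, drives: DriveParams):
    """Net drive to the MA: D_m = nu_mo q_o + a_m (mV).

    With ``nu_mo = 0`` (orexin removed) this is the constant ``a_m``.
    """
    q_o = np.asarray(q_o, dtype=float)
    if np.any(q_o < 0):
        raise ValueError("net_drive_ma: negative orexin firing rate")
    out = coupling.nu_mo * q_o + drives.a_m
    return out if out.ndim else float(out)


def net_drive_orx(c, p: DriveParams, h=0.0):
    """Net drive to Orx: D_o = nu_oc c + nu_oh h + a_o (mV).

    The homeostatic weight ``nu_oh`` is zero by default, so ``h`` only
    matters when that default is explicitly overridden.
    """
    return p.nu_oc * np.asarray(c, float) + p.nu_oh * np.asarray(h, float) + p.a_o


def homeostat_production(q_m, p: HomeostatParams):
    """Saturating H production term mu (1 - exp(-q_m/q_sat)).

    Non-decreasing in q_m, zero at q_m = 0, bounded by mu.
    """
    q_m = np.asarray(q_m, dtype=float)
    out = p.mu * -np.expm1(-q_m / p.q_sat)
    return out if out.ndim else float(out)


def homeostat_rate(h, q_m, p: HomeostatParams):
    """dH/dt = (production(q_m) - h) / chi; pure clearance at q_m = 0."""
    return (homeostat_production(q_m, p) - np.asarray(h, float)) / p.chi


def rhs_full(state: SystemState, p: ModelParameters) -> np.ndarray:
    """Deterministic drift of the full coupled system at ``state``.

    Returns (dV_v, dV_m, dV_o, dH) per second.  Noise is handled by the
    stochastic integrator, never here.
    """
    state.validate()
    q_v = firing_rate(state.v_v, p.sigmoid)
    q_m = firing_rate(state.v_m, p.sigmoid)
    q_o = firing_rate(state.v_o, p.sigmoid)
    c = circadian_drive(state.t, p.drives)
    d_v = net_drive_vlpo(c, state.h, p.drives)
    d_m = net_drive_ma(q_o, p.coupling, p.drives)
    d_o = net_drive_orx(c, p.drives, state.h)
    return np.array([
        (p.coupling.nu_vm * q_m + d_v - state.v_v) / p.tau.tau_v,
        (p.coupling.nu_mv * q_v + d_m - state.v_m) / p.tau.tau_m,
        (p.coupling.nu_ov * q_v + p.coupling.nu_om * q_m + d_o - state.v_o)
        / p.tau.tau_o,
        homeostat_rate(state.h, q_m, p.homeostat),
    ])


def rhs_array(t: float, y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """`solve_ivp`-shaped drift: y = (V_v, V_m, V_o, H)."""
    q_v = firing_rate(y[0], p.sigmoid)
    q_m = firing_rate(y[1], p.sigmoid)
    q_o = firing_rate(y[2], p.sigmoid)
    c = circadian_drive(t, p.drives)
    d_v = net_drive_vlpo(c, y[3], p.drives)
    d_m = p.coupling.nu_mo * q_o + p.drives.a_m
    d_o = net_drive_orx(c, p.drives, y[3])
    return np.array([
        (p.coupling.nu_vm * q_m + d_v - y[0]) / p.tau.tau_v,
        (p.coupling.nu_mv * q_v + d_m - y[1]) / p.tau.tau_m,
        (p.coupling.nu_ov * q_v + p.coupling.nu_om * q_m + d_o - y[2])
        / p.tau.tau_o,
        (homeostat_production(q_m, p.homeostat) - y[3]) / p.homeostat.chi,
    ])


def derived_quantities(times: np.ndarray, states: np.ndarray,
                       p: ModelParameters) -> dict[str, np.ndarray]:
    """Firing rates, circadian value and net drives along a trajectory.

    ``states`` has columns (V_v, V_m, V_o, H).  Everything is computed
    from states + parameters only, so it is bit-for-bit reproducible.
    """
    q_v = firing_rate(states[:, 0], p.sigmoid)
    q_m = firing_rate(states[:, 1], p.sigmoid)
    q_o = firing_rate(states[:, 2], p.sigmoid)
    c = circadian_drive(times, p.drives)
    return {
        "q_v": q_v, "q_m": q_m, "q_o": q_o, "c": c,
        "d_v": net_drive_vlpo(c, states[:, 3], p.drives),
        "d_m": net_drive_ma(q_o, p.coupling, p.drives),
        "d_o": net_drive_orx(c, p.drives, states[:, 3]),
    }
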