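"""Compiled Euler-Maruyama inner loop.

The parameter array layout must match :meth:`ModelParameters.pack`:

    0 q_max  1 theta  2 sigma_prime
    3 nu_vm  4 nu_mv  5 nu_ov  6 nu_mo  7 nu_om
    8 nu_vc  9 nu_vh 10 nu_oc 11 nu_oh
   12 a_v   13 a_m   14 a_o   15 omega 16 phase_ref
   17 chi   18 mu    19 q_sat
   20 tau_v 21 tau_m 22 tau_o
   23 sigma_v 24 sigma_m 25 noise_convention (0 density, 1 per-step)
"""

import numba
import numpy as np


@numba.njit(cache=True)
def _sigmoid(v, q_max, theta, sigma_prime):
    x = (v - theta) / sigma_prime
    if x >= 0.0:
        return q_max / (1.0 + np.exp(-x))
    e = np.exp(x)
    return q_max * e / (1.0 + e)


@numba.njit(cache=True)
def em_integrate(par, y0, t0, n_steps, dt, seed, rec_every, noise_on,
                 force_start, force_end, force_dm):
    """Fixed-step Euler-Maruyama integration.

    Gaussian noise enters the V_v and V_m updates only.  An optional
    constant extra drive ``force_dm`` is added to D_m for
    t in [force_start, force_end) (forced-wake protocols).

    Returns (times, states, final_state, status, t_fail); ``status`` is
    0 on success, 1 if a non-finite state was encountered at ``t_fail``.
    """
    np.random.seed(seed)
    q_max, theta, sp = par[0], par[1], par[2]
    nu_vm, nu_mv, nu_ov, nu_mo, nu_om = par[3], par[4], par[5], par[6], par[7]
    nu_vc, nu_vh, nu_oc, nu_oh = par[8], par[9], par[10], par[11]
    a_v, a_m, a_o, omega, phase_ref = par[12], par[13], par[14], par[15], par[16]
    chi, mu, q_sat = par[17], par[18], par[19]
    tau_v, tau_m, tau_o = par[20], par[21], par[22]
    sigma_v, sigma_m, convention = par[23], par[24], par[25]

    if noise_on:
        if convention == 0.0:      # white-noise density: (sigma/tau) sqrt(dt)
            amp_v = sigma_v * np.sqrt(dt) / tau_v
            amp_m = sigma_m * np.sqrt(dt) / tau_m
        else:                      # per-step sample held over dt
            amp_v = sigma_v * dt / tau_v
            amp_m = sigma_m * dt / tau_m
    else:
        amp_v = 0.0
        amp_m = 0.0

    n_rec = n_steps // rec_every
    times = np.empty(n_rec)
    states = np.empty((n_rec, 4))
    vv, vm, vo, h = y0[0], y0[1], y0[2], y0[3]
    t = t0
    k = 0
    for i in range(n_steps):
        q_v = _sigmoid(vv, q_max, theta, sp)
        q_m = _sigmoid(vm, q_max, theta, sp)
        q_o = _sigmoid(vo, q_max, theta, sp)
        c = np.cos(omega * (t - phase_ref))
        d_v = nu_vc * c + nu_vh * h + a_v
        d_m = nu_mo * q_o + a_m
        if force_start <= t < force_end:
            d_m += force_dm
        d_o = nu_oc * c + nu_oh * h + a_o
        vv += dt * (nu_vm * q_m + d_v - vv) / tau_v
        vm += dt * (nu_mv * q_v + d_m - vm) / tau_m
        if amp_v > 0.0:
            vv += amp_v * np.random.normal()
        if amp_m > 0.0:
            vm += amp_m * np.random.normal()
        vo += dt * (nu_ov * q_v + nu_om * q_m + d_o - vo) / tau_o
        h += dt * (mu * (1.0 - np.exp(-q_m / q_sat)) - h) / chi
        t = t0 + (i + 1) * dt
        if not (np.isfinite(vv) and np.isfinite(vm) and np.isfinite(vo)
                and np.isfinite(h)):
            final = np.array([vv, vm, vo, h])
            return times[:k], states[:k], final, 1, t
        if (i + 1) % rec_every == 0:
            times[k] = t
            states[k, 0] = vv
            states[k, 1] = vm
            states[k, 2] = vo
            states[k, 3] = h
            k += 1
    final = np.array([vv, vm, vo, h])
    return times, states, final, 0, t


@numba.njit(cache=True)
def em_reduced(q_max, theta, sp, nu_vm, nu_mv, tau_v, tau_m,
               amp_v, amp_m, d_v, d_m, y0, n_steps, dt, seed, rec_every):
    """Euler-Maruyama for the frozen-drive two-population subsystem."""
    np.random.seed(seed)
    n_rec = n_steps // rec_every
    times = np.empty(n_rec)
    states = np.empty((n_rec, 2))
    vv, vm = y0[0], y0[1]
    k = 0
    for i in range(n_steps):
        q_v = _sigmoid(vv, q_max, theta, sp)
        q_m = _sigmoid(vm, q_max, theta, sp)
        vv += dt * (nu_vm * q_m + d_v - vv) / tau_v + amp_v * np.random.normal()
        vm += dt * (nu_mv * q_v + d_m - vm) / tau_m + amp_m * np.random.normal()
        if (i + 1) % rec_every == 0:
            times[k] = (i + 1) * dt
            states[k, 0] = vv
            states[k, 1] = vm
            k += 1
    return times, states
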