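"""Compiled Euler-Maruyama integrators for the regional dynamics models.

Each kernel seeds numba's own RNG, integrates at step ``dt``, discards
``burn_steps`` steps and records every ``sample_every``-th step into ``out``
(regions x n_out).  The return value is -1 on success or the index of the
first step at which the state stopped being finite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BLOWUP = 1e9


@njit(cache=True)
def _record_ok(x: np.ndarray) -> bool:
    for i in range(x.shape[0]):
        if not np.isfinite(x[i]) or abs(x[i]) > _BLOWUP:
            return False
    return True


@njit(cache=True)
def rate_kernel(W, G, tau, noise_sd, dt, n_steps, burn_steps, sample_every, seed, out):
    np.random.seed(seed)
    n = W.shape[0]
    x = np.zeros(n)
    sq = noise_sd * np.sqrt(dt)
    rec = 0
    for step in range(n_steps):
        drift = (-x + G * (W @ x)) / tau
        x = x + dt * drift + sq * np.random.standard_normal(n)
        t = step + 1
        if t > burn_steps and (t - burn_steps) % sample_every == 0:
            if not _record_ok(x):
                return step
            if rec < out.shape[1]:
                out[:, rec] = x
                rec += 1
    return -1


@njit(cache=True)
def kuramoto_kernel(W, G, omega, noise_sd, dt, n_steps, burn_steps, sample_every, seed, out):
    np.random.seed(seed)
    n = W.shape[0]
    theta = np.random.uniform(0.0, 2.0 * np.pi, n)
    sq = noise_sd * np.sqrt(dt)
    rec = 0
    for step in range(n_steps):
        s = np.sin(theta)
        c = np.cos(theta)
        # sum_j W_ij sin(theta_j - theta_i) = cos(theta_i)(W s)_i - sin(theta_i)(W c)_i
        coupling = c * (W @ s) - s * (W @ c)
        theta = theta + dt * (omega + G * coupling) + sq * np.random.standard_normal(n)
        t = step + 1
        if t > burn_steps and (t - burn_steps) % sample_every == 0:
            if not _record_ok(theta):
                return step
            if rec < out.shape[1]:
                out[:, rec] = np.sin(theta)
                rec += 1
    return -1


@njit(cache=True)
def wilson_cowan_kernel(
    W, G, tau_e, tau_i, c1, c2, c3, c4, a_e, th_e, a_i, th_i, P,
    noise_sd, dt, n_steps, burn_steps, sample_every, seed, out,
):
    np.random.seed(seed)
    n = W.shape[0]
    E = np.full(n, 0.1)
    I = np.full(n, 0.1)
    sq = noise_sd * np.sqrt(dt)
    rec = 0
    for step in range(n_steps):
        inp_e = c1 * E - c2 * I + G * (W @ E) + P
        inp_i = c3 * E - c4 * I
        Se = 1.0 / (1.0 + np.exp(-a_e * (inp_e - th_e)))
        Si = 1.0 / (1.0 + np.exp(-a_i * (inp_i - th_i)))
        E = E + dt * (-E + Se) / tau_e + sq * np.random.standard_normal(n)
        I = I + dt * (-I + Si) / tau_i
        t = step + 1
        if t > burn_steps and (t - burn_steps) % sample_every == 0:
            if not _record_ok(E):
                return step
            if rec < out.shape[1]:
                out[:, rec] = E
                rec += 1
    return -1


@njit(cache=True)
def fitzhugh_nagumo_kernel(
    W, G, a, b, tau_w, I_ext, speed, noise_sd, dt, n_steps, burn_steps, sample_every, seed, out
):
    np.random.seed(seed)
    n = W.shape[0]
    v = np.random.standard_normal(n) * 0.1
    w = np.zeros(n)
    sq = noise_sd * np.sqrt(dt)
    rec = 0
    for step in range(n_steps):
        dv = speed * (v - v**3 / 3.0 - w + G * (W @ v) + I_ext)
        dw = (speed / tau_w) * (v + a - b * w)
        v = v + dt * dv + sq * np.random.standard_normal(n)
        w = w + dt * dw
        t = step + 1
        if t > burn_steps and (t - burn_steps) % sample_every == 0:
            if not _record_ok(v):
                return step
            if rec < out.shape[1]:
                out[:, rec] = v
                rec += 1
    return -1


@njit(cache=True)
def balloon_kernel(z, kappa, gamma, tau, alpha, E0, V0, dt, out):
    """Balloon-Windkessel hemodynamics, one region per row of ``z``.

    States per region: vasodilatory signal s, inflow f, venous volume v,
    deoxyhemoglobin q; started at the resting fixed point (0, 1, 1, 1).
    ``out`` receives the BOLD percent-signal-change read-out at every input
    sample.  Returns -1, or the (region, step) encoded as region * T + step
    on divergence.
    """
    k1 = 7.0 * E0
    k2 = 2.0
    k3 = 2.0 * E0 - 0.2
    R, T = z.shape
    ialpha = 1.0 / alpha
    for r in range(R):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            ds = z[r, t] - kappa * s - gamma * (f - 1.0)
            df = s
            fv = v**ialpha
            Ef = 1.0 - (1.0 - E0) ** (1.0 / f)
            dv = (f - fv) / tau
            dq = (f * Ef / E0 - fv * q / v) / tau
            s += dt * ds
            f += dt * df
            if f < 0.01:
                f = 0.01
            v += dt * dv
            if v < 0.01:
                v = 0.01
            q += dt * dq
            if not (np.isfinite(s) and np.isfinite(q) and abs(q) < _BLOWUP):
                return r * T + t
            out[r, t] = 100.0 * V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return -1
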