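"""Compiled inner loop for the shell-model Rayleigh-Plesset integration.

A Dormand-Prince 5(4) adaptive step integrator specialised to the
two-state bubble ODE, JIT-compiled with numba so that the 194-point
equilibrium-radius sweeps run in seconds.  The driving pressure is linearly
interpolated on its (uniform) sample grid; outside the recorded waveform it
is zero.  The generic scipy backend in :mod:`sonobubble.bubble` integrates
the identical right-hand side and is used as an independent cross-check.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rp_rhs_params", "integrate_rp"]

# status codes returned by integrate_rp
OK = 0
COLLAPSE = 1
STEP_FAILURE = 2
MAXSTEPS = 3


@njit(cache=True, inline="always")
def _pac(t, p, t0, dtp, n):
    """Linear interpolation of the driving pressure; zero outside the pulse."""
    x = (t - t0) / dtp
    if x <= 0.0 or x >= n - 1:
        return 0.0
    i = int(x)
    frac = x - i
    return p[i] * (1.0 - frac) + p[i + 1] * frac


@njit(cache=True, inline="always")
def _rhs(t, R, Rd, p, t0, dtp, n,
         rho, p0, pv, sigma, chi, gamma3, pg, R0, dcoef):
    """R-acceleration of the corrected shell-model RP equation.

    gamma3 = 3*gamma; dcoef = delta_t * omega (damping term coefficient).
    """
    pac = _pac(t, p, t0, dtp, n)
    bracket = (-1.5 * rho * Rd * Rd
               + pg * (R0 / R) ** gamma3
               + pv - p0
               - 2.0 * sigma / R
               - 2.0 * chi * (1.0 / R0 - 1.0 / R)
               - dcoef * rho * R * Rd
               - pac)
    return bracket / (rho * R)


@njit(cache=True)
def integrate_rp(t_end, R0, p, t0, dtp,
                 rho, p0, pv, sigma, chi, gamma, pg, dcoef,
                 rtol, atol_r, atol_v, max_step, collapse_frac, nmax):
    """Integrate from t=0, R=R0, Rdot=0 to t_end.

    Returns (t_out, R_out, Rd_out, n_accepted, status).
    Preallocated outputs are truncated by the caller using n_accepted.
    """
    n = p.size
    gamma3 = 3.0 * gamma
    t_out = np.empty(nmax)
    R_out = np.empty(nmax)
    Rd_out = np.empty(nmax)

    t = 0.0
    R = R0
    Rd = 0.0
    t_out[0] = t
    R_out[0] = R
    Rd_out[0] = Rd
    m = 1

    h = min(max_step, t_end * 1e-4)
    k1r = Rd
    k1v = _rhs(t, R, Rd, p, t0, dtp, n, rho, p0, pv, sigma, chi, gamma3, pg, R0, dcoef)
    status = OK

    while t < t_end:
        if h > t_end - t:
            h = t_end - t
        # -- Dormand-Prince stages -------------------------------------
        R2 = R + h * 0.2 * k1r
        V2 = Rd + h * 0.2 * k1v
        if R2 <= 0.0:
            h *= 0.5
            if h < 1e-20:
                status = STEP_FAILURE
                break
            continue
        k2r = V2
        k2v = _rhs(t + 0.2 * h, R2, V2, p, t0, dtp, n, rho, p0, pv, sigma, chi, gamma3, pg, R0, dcoef)

        R3 = R + h * (3.0 / 40.0 * k1r + 9.0 / 40.0 * k2r)
        V3 = Rd + h * (3.0 / 40.0 * k1v + 9.0 / 40.0 * k2v)
        if R3 <= 0.0:
            h *= 0.5
            if h < 1e-20:
                status = STEP_FAILURE
                break
            continue
        k3r = V3
        k3v = _rhs(t + 0.3 * h, R3, V3, p, t0, dtp, n, rho, p0, pv, sigma, chi, gamma3, pg, R0, dcoef)

        R4 = R + h * (44.0 / 45.0 * k1r - 56.0 / 15.0 * k2r + 32.0 / 9.0 * k3r)
        V4 = Rd + h * (44.0 / 45.0 * k1v - 56.0 / 15.0 * k2v + 32.0 / 9.0 * k3v)
        if R4 <= 0.0:
            h *= 0.5
            if h < 1e-20:
                status = STEP_FAILURE
                break
            continue
        k4r = V4
        k4v = _rhs(t + 0.8 * h, R4, V4, p, t0, dtp, n, rho, p0, pv, sigma, chi, gamma3, pg, R0, dcoef)

        R5 = R + h * (19372.0 / 6561.0 * k1r - 25360.0 / 2187.0 * k2r
                      + 64448.0 / 6561.0 * k3r - 212.0 / 729.0 * k4r)
        V5 = Rd + h * (19372.0 / 6561.0 * k1v - 25360.0 / 2187.0 * k2v
                       + 64448.0 / 6561.0 * k3v - 212.0 / 729.0 * k4v)
        if R5 <= 0.0:
            h *= 0.5
            if h < 1e-20:
                status = STEP_FAILURE
                break
            continue
        k5r = V5
        k5v = _rhs(t + 8.0 / 9.0 * h, R5, V5, p, t0, dtp, n, rho, p0, pv, sigma, chi, gamma3, pg, R0, dcoef)

        R6 = R + h * (9017.0 / 3168.0 * k1r - 355.0 / 33.0 * k2r
                      + 46732.0 / 5247.0 * k3r + 49.0 / 176.0 * k4r
                      - 5103.0 / 18656.0 * k5r)
        V6 = Rd + h * (9017.0 / 3168.0 * k1v - 355.0 / 33.0 * k2v
                       + 46732.0 / 5247.0 * k3v + 49.0 / 176.0 * k4v
                       - 5103.0 / 18656.0 * k5v)
        if R6 <= 0.0:
            h *= 0.5
            if h < 1e-20:
                status = STEP_FAILURE
                break
            continue
        k6r = V6
        k6v = _rhs(t + h, R6, V6, p, t0, dtp, n, rho, p0, pv, sigma, chi, gamma3, pg, R0, dcoef)

        # 5th-order solution
        Rn = R + h * (35.0 / 384.0 * k1r + 500.0 / 1113.0 * k3r
                      + 125.0 / 192.0 * k4r - 2187.0 / 6784.0 * k5r
                      + 11.0 / 84.0 * k6r)
        Vn = Rd + h * (35.0 / 384.0 * k1v + 500.0 / 1113.0 * k3v
                       + 125.0 / 192.0 * k4v - 2187.0 / 6784.0 * k5v
                       + 11.0 / 84.0 * k6v)
        if Rn <= 0.0:
            h *= 0.5
            if h < 1e-20:
                status = STEP_FAILURE
                break
            continue
        k7r = Vn
        k7v = _rhs(t + h, Rn, Vn, p, t0, dtp, n, rho, p0, pv, sigma, chi, gamma3, pg, R0, dcoef)

        # embedded 4th-order error estimate
        er = h * (71.0 / 57600.0 * k1r - 71.0 / 16695.0 * k3r
                  + 71.0 / 1920.0 * k4r - 17253.0 / 339200.0 * k5r
                  + 22.0 / 525.0 * k6r - 1.0 / 40.0 * k7r)
        ev = h * (71.0 / 57600.0 * k1v - 71.0 / 16695.0 * k3v
                  + 71.0 / 1920.0 * k4v - 17253.0 / 339200.0 * k5v
                  + 22.0 / 525.0 * k6v - 1.0 / 40.0 * k7v)
        sr = atol_r + rtol * max(abs(R), abs(Rn))
        sv = atol_v + rtol * max(abs(Rd), abs(Vn))
        err = np.sqrt(0.5 * ((er / sr) ** 2 + (ev / sv) ** 2))

        if err <= 1.0:
            t += h
            R = Rn
            Rd = Vn
            k1r = k7r   # FSAL
            k1v = k7v
            t_out[m] = t
            R_out[m] = R
            Rd_out[m] = Rd
            m += 1
            if m >= nmax:
                status = MAXSTEPS
                break
            if R < collapse_frac * R0:
                status = COLLAPSE
                break
            fac = 1.25 if err == 0.0 else min(5.0, max(0.2, 0.9 * err ** -0.2))
        else:
            fac = max(0.2, 0.9 * err ** -0.2)
        h = min(h * fac, max_step)
        if h < 1e-20:
            status = STEP_FAILURE
            break

    return t_out[:m], R_out[:m], Rd_out[:m], m, status
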