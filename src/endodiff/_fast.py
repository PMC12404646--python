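"""Numba-compiled hot path: RHS kernels, a Dormand-Prince 5(4) integrator
and the negative log-likelihood kernel.

The public API (`simulate.integrate`, `inference.neg2loglik`) is built on
`scipy.integrate.solve_ivp`; this module provides a numerically equivalent
fast route used inside optimization loops, Sobol sampling and protocol
scans, where hundreds of thousands of trajectory evaluations are needed.
A regression test pins the two routes together to <1e-6 relative.

Integer encodings: lineage 0/1/2 = M1/M2/M3, growth 0/1/2 =
exponential/logistic/gompertz.  Structural parameters arrive as a flat
array in the canonical order of `model_core._STRUCT_PARAMS` (without
nmax, which is passed separately; ignored for exponential growth).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOMPERTZ_FLOOR = 1e-12
_BLOWUP = 1e12
_MAX_STEPS = 200_000

# status codes
OK = 0
BLOWUP = 1
TOO_MANY_STEPS = 2


@njit(cache=True, inline="always")
def _fgrow(gro, n, nmax):
    if gro == 0:
        return 1.0
    if gro == 1:
        return 1.0 - n / nmax
    return np.log(nmax / max(n, _GOMPERTZ_FLOOR))


@njit(cache=True)
def _rhs(lin, gro, y, th, nmax, out):
    _rhs_raw(lin, gro, y, th, nmax, out)
    # nonnegativity projection: a depleted compartment cannot keep
    # draining (above carrying capacity the symmetric-division transfer
    # rate turns negative); keeps trajectories restart-invariant
    for j in range(y.shape[0]):
        if y[j] <= 0.0 and out[j] < 0.0:
            out[j] = 0.0


@njit(cache=True, inline="always")
def _rhs_raw(lin, gro, y, th, nmax, out):
    if lin == 0:
        ns = max(y[0], 0.0)
        nd = max(y[1], 0.0)
        bs = th[0] * _fgrow(gro, ns, nmax)
        bd = th[3] * _fgrow(gro, nd, nmax)
        psd = 2.0 * (1.0 - th[1]) * bs
        out[0] = bs * ns - th[2] * ns - psd * ns
        out[1] = bd * nd - th[4] * nd + psd * ns
        out[2] = th[2] * ns + th[4] * nd
    elif lin == 1:
        ns = max(y[0], 0.0)
        nt = max(y[1], 0.0)
        nd = max(y[2], 0.0)
        bs = th[0] * _fgrow(gro, ns, nmax)
        bt = th[3] * _fgrow(gro, nt, nmax)
        bd = th[6] * _fgrow(gro, nd, nmax)
        pst = 2.0 * (1.0 - th[1]) * bs
        ptd = 2.0 * (1.0 - th[4]) * bt
        out[0] = bs * ns - th[2] * ns - pst * ns
        out[1] = bt * nt - th[5] * nt + pst * ns - ptd * nt
        out[2] = bd * nd - th[7] * nd + ptd * nt
        out[3] = th[2] * ns + th[5] * nt + th[7] * nd
    else:
        ns = max(y[0], 0.0)
        nt1 = max(y[1], 0.0)
        nt2 = max(y[2], 0.0)
        nd = max(y[3], 0.0)
        bs = th[0] * _fgrow(gro, ns, nmax)
        bt1 = th[4] * _fgrow(gro, nt1, nmax)
        bt2 = th[7] * _fgrow(gro, nt2, nmax)
        bd = th[10] * _fgrow(gro, nd, nmax)
        pst1 = 2.0 * (1.0 - th[1]) * th[2] * bs
        pst2 = 2.0 * (1.0 - th[1]) * (1.0 - th[2]) * bs
        pt1d = 2.0 * (1.0 - th[5]) * bt1
        pt2d = 2.0 * (1.0 - th[8]) * bt2
        out[0] = bs * ns - th[3] * ns - pst1 * ns - pst2 * ns
        out[1] = bt1 * nt1 - th[6] * nt1 + pst1 * ns - pt1d * nt1
        out[2] = bt2 * nt2 - th[9] * nt2 + pst2 * ns - pt2d * nt2
        out[3] = bd * nd - th[11] * nd + pt1d * nt1 + pt2d * nt2
        out[4] = th[3] * ns + th[6] * nt1 + th[9] * nt2 + th[11] * nd


# Dormand-Prince 5(4) coefficients
_C2, _C3, _C4, _C5 = 0.2, 0.3, 0.8, 8.0 / 9.0
_A21 = 0.2
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0,
    49.0 / 176.0, -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
    -2187.0 / 6784.0, 11.0 / 84.0,
)
# b - bhat (embedded 4th-order error weights)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0, -71.0 / 16695.0, 71.0 / 1920.0,
    -17253.0 / 339200.0, 22.0 / 525.0, -1.0 / 40.0,
)


@njit(cache=True)
def integrate_grid(lin, gro, th, nmax, y0, t_out, rtol, atol):
    """Integrate from t=t_out[0] hitting every t_out exactly.

    Returns (states at t_out, status).  States are clipped to >= 0 on
    output.  t_out must be strictly increasing; y0 is the state at
    t_out[0].
    """
    n = y0.shape[0]
    m = t_out.shape[0]
    out = np.empty((m, n))
    y = y0.copy()
    for j in range(n):
        out[0, j] = max(y[j], 0.0)

    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)

    t = t_out[0]
    h = 0.01
    _rhs(lin, gro, y, th, nmax, k1)
    nsteps = 0
    for iout in range(1, m):
        t_end = t_out[iout]
        while t < t_end:
            nsteps += 1
            if nsteps > _MAX_STEPS:
                return out, TOO_MANY_STEPS
            if h > t_end - t:
                h = t_end - t
            # stages (FSAL: k1 already holds f(t, y))
            for j in range(n):
                ytmp[j] = y[j] + h * _A21 * k1[j]
            _rhs(lin, gro, ytmp, th, nmax, k2)
            for j in range(n):
                ytmp[j] = y[j] + h * (_A31 * k1[j] + _A32 * k2[j])
            _rhs(lin, gro, ytmp, th, nmax, k3)
            for j in range(n):
                ytmp[j] = y[j] + h * (
                    _A41 * k1[j] + _A42 * k2[j] + _A43 * k3[j]
                )
            _rhs(lin, gro, ytmp, th, nmax, k4)
            for j in range(n):
                ytmp[j] = y[j] + h * (
                    _A51 * k1[j] + _A52 * k2[j] + _A53 * k3[j] + _A54 * k4[j]
                )
            _rhs(lin, gro, ytmp, th, nmax, k5)
            for j in range(n):
                ytmp[j] = y[j] + h * (
                    _A61 * k1[j] + _A62 * k2[j] + _A63 * k3[j]
                    + _A64 * k4[j] + _A65 * k5[j]
                )
            _rhs(lin, gro, ytmp, th, nmax, k6)
            for j in range(n):
                ynew[j] = y[j] + h * (
                    _B1 * k1[j] + _B3 * k3[j] + _B4 * k4[j]
                    + _B5 * k5[j] + _B6 * k6[j]
                )
            _rhs(lin, gro, ynew, th, nmax, k7)
            # error norm
            errnorm = 0.0
            for j in range(n):
                e = h * (
                    _E1 * k1[j] + _E3 * k3[j] + _E4 * k4[j]
                    + _E5 * k5[j] + _E6 * k6[j] + _E7 * k7[j]
                )
                sc = atol + rtol * max(abs(y[j]), abs(ynew[j]))
                errnorm += (e / sc) ** 2
            errnorm = np.sqrt(errnorm / n)
            if errnorm <= 1.0:
                t += h
                for j in range(n):
                    y[j] = ynew[j]
                    k1[j] = k7[j]
                if not np.isfinite(y).all() or np.abs(y).max() > _BLOWUP:
                    return out, BLOWUP
                if errnorm == 0.0:
                    fac = 5.0
                else:
                    fac = min(5.0, max(0.2, 0.9 * errnorm ** -0.2))
                h *= fac
            else:
                if not np.isfinite(errnorm):
                    h *= 0.2
                else:
                    h *= max(0.2, 0.9 * errnorm ** -0.2)
                if h < 1e-14:
                    return out, BLOWUP
        for j in range(n):
            out[iout, j] = max(y[j], 0.0)
    return out, OK


@njit(cache=True)
def neg2loglik_packed(
    lin, gro, err_id, th, nmax, a, b,
    y0_mat, t_obs, z_obs, obs_mask,
    state_mask, sigma_min, rtol, atol,
):
    """-2 log-likelihood over packed replicate data.

    y0_mat: (n_rep, n_states) initial states at t_obs[r, 0].
    t_obs: (n_rep, n_t) observation times (first entry = day 0, excluded
    from the sums; trailing slots may repeat the last time, masked out).
    z_obs: (n_rep, n_t, n_states) observed values (NaN = absent).
    obs_mask: (n_rep, n_t) which time slots are real.
    state_mask: (n_states,) which observables enter the sums (common-state
    restriction sets this to ns/nd/nq only).

    Returns (loss, status, n_used, n_floored).
    """
    n_rep, n_t = t_obs.shape
    loss = 0.0
    n_used = 0
    n_floor = 0
    for r in range(n_rep):
        traj, status = integrate_grid(
            lin, gro, th, nmax, y0_mat[r], t_obs[r], rtol, atol
        )
        if status != OK:
            return np.inf, status, n_used, n_floor
        for it in range(1, n_t):
            if not obs_mask[r, it]:
                continue
            for js in range(z_obs.shape[2]):
                if not state_mask[js]:
                    continue
                z = z_obs[r, it, js]
                if np.isnan(z):
                    continue
                g = traj[it, js]
                if err_id == 0:
                    eps = a
                elif err_id == 1:
                    eps = b * g
                else:
                    eps = a + b * g
                if eps < sigma_min:
                    eps = sigma_min
                    n_floor += 1
                resid = (z - g) / eps
                loss += resid * resid + 2.0 * np.log(eps)
                n_used += 1
    return loss, OK, n_used, n_floor


LINEAGE_ID = {"M1": 0, "M2": 1, "M3": 2}
GROWTH_ID = {"exponential": 0, "logistic": 1, "gompertz": 2}
ERROR_ID = {"additive": 0, "proportional": 1, "combined": 2}
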