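"""Low-level batch integration kernels for the neuronal + hemodynamic system.

The state of each region is ``[x, s, ln f, ln v, ln q]``: neuronal activity,
vasodilatory signal, and log-transformed blood flow, venous volume and
deoxyhemoglobin content.  Flow/volume/dHb are integrated in log space so that
they stay positive even for aggressive parameter proposals during inversion.

Kernels are compiled with numba and operate on a *batch* of parameter sets at
once; the subject-level inversion exploits this to obtain finite-difference
Jacobians at roughly the cost of a single forward integration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: state indices
_IX, _IS, _ILF, _ILV, _ILQ = 0, 1, 2, 3, 4

SELF_LINEAR = 0  #: diagonal of (A + u2 B) used verbatim (literal bilinear form)
SELF_LOG = 1     #: effective self-connection = -0.5 * exp(diagonal)

METHOD_EULER = 0
METHOD_RK4 = 1


@njit(cache=True, error_model="numpy")
def _deriv(state, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0, log1me0, self_mode, out):
    nb = state.shape[0]
    for i in range(nb):
        for j in range(3):
            dx = 0.0
            for k in range(3):
                m = A[i, j, k] + u2 * B[i, j, k]
                if j == k:
                    if self_mode == SELF_LOG:
                        m = -0.5 * np.exp(m)
                dx += m * state[i, k, _IX]
            dx += C[i, j, 0] * u1 + C[i, j, 1] * u2
            x = state[i, j, _IX]
            s = state[i, j, _IS]
            # clamp log-states for the derivative evaluation: outside this
            # range the balloon model has left its physiological regime and
            # an unclamped 1/f (etc.) term is numerically singular
            lf = min(max(state[i, j, _ILF], -6.0), 6.0)
            lv = min(max(state[i, j, _ILV], -6.0), 6.0)
            lq = min(max(state[i, j, _ILQ], -6.0), 6.0)
            f = np.exp(lf)
            v = np.exp(lv)
            q = np.exp(lq)
            fv = np.exp(lv / alpha)                 # v ** (1/alpha)
            ef = 1.0 - np.exp(log1me0 / f)          # 1 - (1-E0) ** (1/f)
            tj = tau[i, j]
            out[i, j, _IX] = dx
            out[i, j, _IS] = x - kappa * s - gamma * (f - 1.0)
            out[i, j, _ILF] = s / f
            out[i, j, _ILV] = (f - fv) / (tj * v)
            out[i, j, _ILQ] = (f * ef / e0 - fv * q / v) / (tj * q)


@njit(cache=True, error_model="numpy")
def _bold(state, v0, k1, k2, k3, out_y, scan, nb):
    for i in range(nb):
        for j in range(3):
            v = np.exp(min(max(state[i, j, _ILV], -6.0), 6.0))
            q = np.exp(min(max(state[i, j, _ILQ], -6.0), 6.0))
            out_y[i, scan, j] = 100.0 * v0 * (
                k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v)
            )


@njit(cache=True, error_model="numpy")
def integrate_session(A, B, C, tau, U, dt, scan_idx, kappa, gamma, alpha, e0,
                      v0, k1, k2, k3, self_mode, method, x_bound):
    """Integrate one session for a batch of parameter sets.

    Parameters
    ----------
    A, B, C : (nb, 3, 3), (nb, 3, 3), (nb, 3, 2)
        Connectivity parameter arrays, one slice per batch member.
    tau : (nb, 3)
        Transit time per region and batch member (seconds).
    U : (nt, 2)
        Condition box-car inputs on the microtime grid (u1 = TTNF, u2 = TT).
    scan_idx : (nscan,) int64
        Microtime indices at which BOLD observations are recorded.

    Returns
    -------
    y : (nb, nscan, 3) BOLD observations (percent signal change).
    status : (nb,) int64, 0 = ok, 1 = diverged (|x| exceeded ``x_bound``).
    fail_t : (nb,) float64, time of divergence (NaN when status == 0).
    """
    nb = A.shape[0]
    nt = U.shape[0]
    nscan = scan_idx.shape[0]
    log1me0 = np.log(1.0 - e0)
    state = np.zeros((nb, 3, 5))
    y = np.zeros((nb, nscan, 3))
    status = np.zeros(nb, dtype=np.int64)
    fail_t = np.full(nb, np.nan)
    k1s = np.zeros((nb, 3, 5))
    k2s = np.zeros((nb, 3, 5))
    k3s = np.zeros((nb, 3, 5))
    k4s = np.zeros((nb, 3, 5))
    tmp = np.zeros((nb, 3, 5))
    scan = 0
    for n in range(nt):
        while scan < nscan and scan_idx[scan] == n:
            _bold(state, v0, k1, k2, k3, y, scan, nb)
            scan += 1
        u1 = U[n, 0]
        u2 = U[n, 1]
        if method == METHOD_EULER:
            _deriv(state, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k1s)
            for i in range(nb):
                if status[i] == 0:
                    for j in range(3):
                        for m in range(5):
                            state[i, j, m] += dt * k1s[i, j, m]
        else:
            _deriv(state, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k1s)
            for i in range(nb):
                for j in range(3):
                    for m in range(5):
                        tmp[i, j, m] = state[i, j, m] + 0.5 * dt * k1s[i, j, m]
            _deriv(tmp, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k2s)
            for i in range(nb):
                for j in range(3):
                    for m in range(5):
                        tmp[i, j, m] = state[i, j, m] + 0.5 * dt * k2s[i, j, m]
            _deriv(tmp, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k3s)
            for i in range(nb):
                for j in range(3):
                    for m in range(5):
                        tmp[i, j, m] = state[i, j, m] + dt * k3s[i, j, m]
            _deriv(tmp, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k4s)
            for i in range(nb):
                if status[i] == 0:
                    for j in range(3):
                        for m in range(5):
                            state[i, j, m] += dt / 6.0 * (
                                k1s[i, j, m] + 2.0 * k2s[i, j, m]
                                + 2.0 * k3s[i, j, m] + k4s[i, j, m])
        for i in range(nb):
            if status[i] == 0:
                for j in range(3):
                    if abs(state[i, j, _IX]) > x_bound:
                        status[i] = 1
                        fail_t[i] = (n + 1) * dt
                    for m in range(5):
                        if not np.isfinite(state[i, j, m]):
                            status[i] = 1
                            fail_t[i] = (n + 1) * dt
    while scan < nscan:
        _bold(state, v0, k1, k2, k3, y, scan, nb)
        scan += 1
    return y, status, fail_t


@njit(cache=True, error_model="numpy")
def integrate_session_states(A, B, C, tau, U, dt, kappa, gamma, alpha, e0,
                             self_mode, method, x_bound):
    """As :func:`integrate_session` but returning the full state trajectory.

    Returns states of shape ``(nb, nt + 1, 3, 5)`` on the microtime grid
    (log-transformed hemodynamic states), plus status/fail arrays.
    """
    nb = A.shape[0]
    nt = U.shape[0]
    log1me0 = np.log(1.0 - e0)
    traj = np.zeros((nb, nt + 1, 3, 5))
    state = np.zeros((nb, 3, 5))
    status = np.zeros(nb, dtype=np.int64)
    fail_t = np.full(nb, np.nan)
    k1s = np.zeros((nb, 3, 5))
    k2s = np.zeros((nb, 3, 5))
    k3s = np.zeros((nb, 3, 5))
    k4s = np.zeros((nb, 3, 5))
    tmp = np.zeros((nb, 3, 5))
    for n in range(nt):
        u1 = U[n, 0]
        u2 = U[n, 1]
        if method == METHOD_EULER:
            _deriv(state, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k1s)
            for i in range(nb):
                if status[i] == 0:
                    for j in range(3):
                        for m in range(5):
                            state[i, j, m] += dt * k1s[i, j, m]
        else:
            _deriv(state, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k1s)
            for i in range(nb):
                for j in range(3):
                    for m in range(5):
                        tmp[i, j, m] = state[i, j, m] + 0.5 * dt * k1s[i, j, m]
            _deriv(tmp, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k2s)
            for i in range(nb):
                for j in range(3):
                    for m in range(5):
                        tmp[i, j, m] = state[i, j, m] + 0.5 * dt * k2s[i, j, m]
            _deriv(tmp, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k3s)
            for i in range(nb):
                for j in range(3):
                    for m in range(5):
                        tmp[i, j, m] = state[i, j, m] + dt * k3s[i, j, m]
            _deriv(tmp, A, B, C, u1, u2, kappa, gamma, tau, alpha, e0,
                   log1me0, self_mode, k4s)
            for i in range(nb):
                if status[i] == 0:
                    for j in range(3):
                        for m in range(5):
                            state[i, j, m] += dt / 6.0 * (
                                k1s[i, j, m] + 2.0 * k2s[i, j, m]
                                + 2.0 * k3s[i, j, m] + k4s[i, j, m])
        for i in range(nb):
            if status[i] == 0:
                for j in range(3):
                    if abs(state[i, j, _IX]) > x_bound:
                        status[i] = 1
                        fail_t[i] = (n + 1) * dt
                    for m in range(5):
                        if not np.isfinite(state[i, j, m]):
                            status[i] = 1
                            fail_t[i] = (n + 1) * dt
            for j in range(3):
                for m in range(5):
                    traj[i, n + 1, j, m] = state[i, j, m]
    return traj, status, fail_t
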