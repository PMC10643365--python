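"""Compiled inner loops for the forward model.

The neural system is linear and piecewise-constant in its input, so each
microtime bin is advanced exactly with a precomputed matrix exponential.
The haemodynamic (balloon) ODEs are nonlinear and are advanced with RK4 on
the same grid, holding the neural drive constant within each bin.

Everything here is batched over a leading axis so that a finite-difference
Jacobian (2p+1 perturbed parameter vectors) costs a single pass.
"""

import numpy as np
from numba import njit

#: divergence guard for neural trajectories
X_LIMIT = 1.0e6


@njit(cache=True)
def neural_batch(E, M, u):
    """Advance dx/dt = A x + c u exactly per microtime bin.

    Parameters
    ----------
    E : (B, R, R) matrix exponentials exp(A*dt), one per batch row.
    M : (B, R) integrated input term A^{-1}(exp(A*dt)-I) c.
    u : (T,) input level per bin (held constant within a bin).

    Returns
    -------
    x : (B, T+1, R) neural states at bin edges, x[:, 0] = 0.
    ok : (B,) False where the trajectory exceeded the divergence guard.
    """
    B, R = M.shape
    T = u.shape[0]
    x = np.zeros((B, T + 1, R))
    ok = np.ones(B, np.bool_)
    for b in range(B):
        for t in range(T):
            for i in range(R):
                acc = M[b, i] * u[t]
                for j in range(R):
                    acc += E[b, i, j] * x[b, t, j]
                x[b, t + 1, i] = acc
                if np.abs(acc) > X_LIMIT:
                    ok[b] = False
            if not ok[b]:
                break
    return x, ok


@njit(cache=True)
def hemo_batch(x, kappa, tau, gamma, alpha, e0, obs, k1, k2, k3, dt):
    """Balloon-Windkessel haemodynamics driven by neural states.

    State per region: vasodilatory signal s, inflow f, venous volume v,
    deoxyhemoglobin q, starting from the resting fixed point (0, 1, 1, 1).
    The drive is held at x[:, t] over bin t.  Output is the BOLD signal
    y = obs * (k1(1-q) + k2(1-q/v) + k3(1-v)) with obs the combined
    observation coefficient (resting volume fraction x unit scale);
    y[:, t] is evaluated from the state at the start of bin t, so
    y[:, 0] = 0 at rest.

    Returns (y, ok); ok is False where f, v or q left the positive domain.
    """
    B, Tp1, R = x.shape
    T = Tp1 - 1
    ialpha = 1.0 / alpha
    y = np.zeros((B, Tp1, R))
    ok = np.ones(B, np.bool_)
    for b in range(B):
        s = np.zeros(R)
        f = np.ones(R)
        v = np.ones(R)
        q = np.ones(R)
        for t in range(T + 1):
            for i in range(R):
                y[b, t, i] = obs * (
                    k1 * (1.0 - q[i])
                    + k2 * (1.0 - q[i] / v[i])
                    + k3 * (1.0 - v[i])
                )
            if t == T:
                break
            for i in range(R):
                xi = x[b, t, i]
                ki = kappa[b, i]
                ti = tau[b, i]
                # RK4 with drive xi constant over the bin
                s0, f0, v_0, q0 = s[i], f[i], v[i], q[i]
                bad = False
                ds1, df1, dv1, dq1 = _hemo_rhs(xi, s0, f0, v_0, q0, ki, ti,
                                               gamma, ialpha, e0)
                s1 = s0 + 0.5 * dt * ds1
                f1 = f0 + 0.5 * dt * df1
                v1 = v_0 + 0.5 * dt * dv1
                q1 = q0 + 0.5 * dt * dq1
                if f1 <= 0.0 or v1 <= 0.0 or q1 <= 0.0:
                    bad = True
                else:
                    ds2, df2, dv2, dq2 = _hemo_rhs(xi, s1, f1, v1, q1, ki, ti,
                                                   gamma, ialpha, e0)
                    s2 = s0 + 0.5 * dt * ds2
                    f2 = f0 + 0.5 * dt * df2
                    v2 = v_0 + 0.5 * dt * dv2
                    q2 = q0 + 0.5 * dt * dq2
                    if f2 <= 0.0 or v2 <= 0.0 or q2 <= 0.0:
                        bad = True
                    else:
                        ds3, df3, dv3, dq3 = _hemo_rhs(xi, s2, f2, v2, q2, ki,
                                                       ti, gamma, ialpha, e0)
                        s3 = s0 + dt * ds3
                        f3 = f0 + dt * df3
                        v3 = v_0 + dt * dv3
                        q3 = q0 + dt * dq3
                        if f3 <= 0.0 or v3 <= 0.0 or q3 <= 0.0:
                            bad = True
                        else:
                            ds4, df4, dv4, dq4 = _hemo_rhs(
                                xi, s3, f3, v3, q3, ki, ti, gamma, ialpha, e0)
                            s[i] = s0 + dt / 6.0 * (ds1 + 2 * ds2 + 2 * ds3 + ds4)
                            f[i] = f0 + dt / 6.0 * (df1 + 2 * df2 + 2 * df3 + df4)
                            v[i] = v_0 + dt / 6.0 * (dv1 + 2 * dv2 + 2 * dv3 + dv4)
                            q[i] = q0 + dt / 6.0 * (dq1 + 2 * dq2 + 2 * dq3 + dq4)
                            if f[i] <= 0.0 or v[i] <= 0.0 or q[i] <= 0.0:
                                bad = True
                if bad:
                    ok[b] = False
                    break
            if not ok[b]:
                break
    return y, ok


@njit(cache=True, inline="always")
def _hemo_rhs(x, s, f, v, q, kappa, tau, gamma, ialpha, e0):
    fv = v ** ialpha
    ds = x - kappa * s - gamma * (f - 1.0)
    df = s
    dv = (f - fv) / tau
    dq = (f * (1.0 - (1.0 - e0) ** (1.0 / f)) / e0 - fv * q / v) / tau
    return ds, df, dv, dq
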