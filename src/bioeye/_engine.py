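"""Numba-compiled numerical core for the plant simulator and control costs.

Everything here operates on plain float64 arrays; the friendly dataclass
surface lives in :mod:`bioeye.plant` and :mod:`bioeye.control`.  Units:
lengths mm, forces N, torques N*mm, inertia kg*mm^2, angular velocity rad/s,
orientations as Euler-Rodrigues rotation vectors (rad/2), time step s.

With torque in N*mm and inertia in kg*mm^2 the angular acceleration is
``1000 * I^-1 (tau - 1e-3 * w x (I w))`` rad/s^2 (the factor pair converts
both mixed-unit terms to SI and back).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------- kinematics


@njit(cache=True, fastmath=True)
def _rotmat(r):
    """Rotation matrix of rotation vector r (eye frame -> head frame)."""
    n2 = r[0] * r[0] + r[1] * r[1] + r[2] * r[2]
    s = 2.0 / (1.0 + n2)
    rx, ry, rz = r[0], r[1], r[2]
    R = np.empty((3, 3))
    R[0, 0] = 1.0 + s * (-(ry * ry + rz * rz))
    R[0, 1] = s * (rx * ry - rz)
    R[0, 2] = s * (rx * rz + ry)
    R[1, 0] = s * (rx * ry + rz)
    R[1, 1] = 1.0 + s * (-(rx * rx + rz * rz))
    R[1, 2] = s * (ry * rz - rx)
    R[2, 0] = s * (rx * rz - ry)
    R[2, 1] = s * (ry * rz + rx)
    R[2, 2] = 1.0 + s * (-(rx * rx + ry * ry))
    return R


@njit(cache=True, fastmath=True)
def _cross(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True, fastmath=True)
def _rdot_from_omega(r, w):
    wr = w[0] * r[0] + w[1] * r[1] + w[2] * r[2]
    c = _cross(w, r)
    out = np.empty(3)
    for i in range(3):
        out[i] = 0.5 * (w[i] + c[i] + wr * r[i])
    return out


@njit(cache=True, fastmath=True)
def _solve3(A, b):
    """Solve the symmetric positive-definite 3x3 system A x = b (Cramer)."""
    a00, a01, a02 = A[0, 0], A[0, 1], A[0, 2]
    a10, a11, a12 = A[1, 0], A[1, 1], A[1, 2]
    a20, a21, a22 = A[2, 0], A[2, 1], A[2, 2]
    det = (a00 * (a11 * a22 - a12 * a21)
           - a01 * (a10 * a22 - a12 * a20)
           + a02 * (a10 * a21 - a11 * a20))
    x = np.empty(3)
    x[0] = (b[0] * (a11 * a22 - a12 * a21)
            - a01 * (b[1] * a22 - a12 * b[2])
            + a02 * (b[1] * a21 - a11 * b[2])) / det
    x[1] = (a00 * (b[1] * a22 - a12 * b[2])
            - b[0] * (a10 * a22 - a12 * a20)
            + a02 * (a10 * b[2] - b[1] * a20)) / det
    x[2] = (a00 * (a11 * b[2] - b[1] * a21)
            - a01 * (a10 * b[2] - b[1] * a20)
            + b[0] * (a10 * a21 - a11 * a20)) / det
    return x


# ----------------------------------------------------------------- dynamics


@njit(cache=True, fastmath=True)
def tensions_and_torque(r, w, u, ins, anch, L0, gains, k, tpre, damping):
    """Per-tendon tensions (N, slack-clamped at 0) and net torque (N*mm).

    ``ins`` (3,6) eye-frame insertions, ``anch`` (3,6) head-frame anchor
    (origin or pulley) points, ``L0`` rest path lengths at r=0, ``u`` (6,)
    commanded cable shortenings (command units; ``gains`` converts to mm).
    """
    R = _rotmat(r)
    tens = np.empty(6)
    tau = np.zeros(3)
    for i in range(6):
        p = np.empty(3)
        for a in range(3):
            p[a] = R[a, 0] * ins[0, i] + R[a, 1] * ins[1, i] + R[a, 2] * ins[2, i]
        d = np.empty(3)
        for a in range(3):
            d[a] = anch[a, i] - p[a]
        L = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        stretch = L - L0[i]
        T = tpre + k * (stretch + gains[i] * u[i])
        if T < 0.0:
            T = 0.0  # muscles pull, never push
        tens[i] = T
        f = T / L
        tq = _cross(p, d)
        for a in range(3):
            tau[a] += f * tq[a]
    tau[0] -= damping * w[0]
    tau[1] -= damping * w[1]
    tau[2] -= damping * w[2]
    return tens, tau


@njit(cache=True, fastmath=True)
def _inertia_head(r, inertia_diag):
    """Head-frame inertia tensor I(r) = R diag(I) R^T."""
    R = _rotmat(r)
    Ih = np.empty((3, 3))
    for a in range(3):
        for b in range(3):
            s = 0.0
            for c in range(3):
                s += R[a, c] * inertia_diag[c] * R[b, c]
            Ih[a, b] = s
    return Ih


@njit(cache=True, fastmath=True)
def _accel(r, w, tau, inertia_diag):
    """Explicit angular acceleration (rad/s^2); ``tau`` is the full torque
    (muscles + damping) in N*mm.  Used by the RK4 reference integrator."""
    Ih = _inertia_head(r, inertia_diag)
    Iw = np.empty(3)
    for a in range(3):
        Iw[a] = Ih[a, 0] * w[0] + Ih[a, 1] * w[1] + Ih[a, 2] * w[2]
    gyro = _cross(w, Iw)
    rhs = np.empty(3)
    for a in range(3):
        rhs[a] = 1000.0 * tau[a] - 0.001 * gyro[a]
    return _solve3(Ih, rhs)


@njit(cache=True, fastmath=True)
def simulate_core(u, r0, w0, ins, anch, L0, gains, k, tpre, damping,
                  inertia_diag, dt, nsub):
    """Semi-implicit Euler integration of the plant at sample step ``dt``.

    The plant is viscosity-dominated (the velocity relaxation time I/B is far
    below the 1 ms sample), so the damping torque is treated implicitly:

        (I(r) + 1000 h B Id) w+ = I(r) w + h (1000 tau_muscle - 1e-3 gyro)

    which is unconditionally stable in the stiff direction; ``nsub`` substeps
    of h = dt/nsub refine the slow orientation dynamics.  Commands are held
    constant within a sample (zero-order hold).

    ``u`` is (6, T); the trajectory has T samples, sample 0 being the initial
    state.  Returns (r, w, rdot, tensions) with shapes (T,3),(T,3),(T,3),(T,6).
    """
    T = u.shape[1]
    rs = np.empty((T, 3))
    ws = np.empty((T, 3))
    rds = np.empty((T, 3))
    tns = np.empty((T, 6))
    r = r0.copy()
    w = w0.copy()
    h = dt / nsub
    for t in range(T):
        tens, tau = tensions_and_torque(r, w, u[:, t], ins, anch, L0, gains,
                                        k, tpre, damping)
        rs[t] = r
        ws[t] = w
        rds[t] = _rdot_from_omega(r, w)
        tns[t] = tens
        if t == T - 1:
            break
        for _ in range(nsub):
            tens_s, tau_s = tensions_and_torque(
                r, w, u[:, t], ins, anch, L0, gains, k, tpre, damping)
            # tau_s includes -B w; recover the muscle-only torque
            Ih = _inertia_head(r, inertia_diag)
            Iw = np.empty(3)
            for a in range(3):
                Iw[a] = Ih[a, 0] * w[0] + Ih[a, 1] * w[1] + Ih[a, 2] * w[2]
            gyro = _cross(w, Iw)
            A = np.empty((3, 3))
            rhs = np.empty(3)
            bh = 1000.0 * h * damping
            for a in range(3):
                for b in range(3):
                    A[a, b] = Ih[a, b]
                A[a, a] += bh
                tau_m = tau_s[a] + damping * w[a]
                rhs[a] = Iw[a] + h * (1000.0 * tau_m - 0.001 * gyro[a])
            w = _solve3(A, rhs)
            rd = _rdot_from_omega(r, w)
            rn = np.empty(3)
            for a in range(3):
                rn[a] = r[a] + h * rd[a]
            r = rn
    return rs, ws, rds, tns


# -------------------------------------------------------------- control cost


@njit(cache=True, fastmath=True)
def _interp_knots(knots, knot_ms, T):
    """Linear interpolation of (6, nk) knots (spaced knot_ms samples) to (6, T)."""
    u = np.empty((6, T))
    nk = knots.shape[1]
    for t in range(T):
        x = t / knot_ms
        j = int(x)
        if j >= nk - 1:
            for i in range(6):
                u[i, t] = knots[i, nk - 1]
        else:
            frac = x - j
            for i in range(6):
                u[i, t] = knots[i, j] * (1.0 - frac) + knots[i, j + 1] * frac
    return u


@njit(cache=True, fastmath=True)
def movement_cost(knots, knot_ms, T, r0, w0, rg,
                  ins, anch, L0, gains, k, tpre, damping, inertia_diag, dt,
                  nsub, lam_a, lam_e, w_omega):
    """Accuracy + energy part of the movement cost for a knotted command.

    Returns (lam_a*J_A + lam_e*J_E, J_A, J_E).  The duration cost depends on
    D only and is added by the caller.
    """
    u = _interp_knots(knots, knot_ms, T)
    rs, ws, rds, tns = simulate_core(u, r0, w0, ins, anch, L0, gains, k, tpre,
                                     damping, inertia_diag, dt, nsub)
    ja = 0.0
    for a in range(3):
        e = rs[T - 1, a] - rg[a]
        ja += e * e
        ja += w_omega * ws[T - 1, a] * ws[T - 1, a]
    je = 0.0
    for t in range(T - 1):
        for i in range(6):
            du = (u[i, t + 1] - u[i, t]) / dt
            je += du * du * dt
    return lam_a * ja + lam_e * je, ja, je


@njit(cache=True, fastmath=True)
def cost_and_grad(theta, knot_ms, T, r0, w0, rg,
                  ins, anch, L0, gains, k, tpre, damping, inertia_diag, dt,
                  nsub, lam_a, lam_e, w_omega, h):
    """Cost and forward-difference gradient over the flattened knot vector."""
    nk = theta.shape[0] // 6
    knots = theta.reshape(6, nk)
    j0, _, _ = movement_cost(knots, knot_ms, T, r0, w0, rg, ins, anch, L0,
                             gains, k, tpre, damping, inertia_diag, dt,
                             nsub, lam_a, lam_e, w_omega)
    g = np.empty(theta.shape[0])
    for m in range(theta.shape[0]):
        old = theta[m]
        theta[m] = old + h
        kn = theta.reshape(6, nk)
        j1, _, _ = movement_cost(kn, knot_ms, T, r0, w0, rg, ins, anch, L0,
                                 gains, k, tpre, damping, inertia_diag, dt,
                                 nsub, lam_a, lam_e, w_omega)
        g[m] = (j1 - j0) / h
        theta[m] = old
    return j0, g
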