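"""Numba kernels for the staggered-grid fractional-step solver.

Conventions: velocity component arrays are passed with their own axis
permuted to axis 0, so one kernel serves u, v and w.  For the permuted
component ``u`` of shape (n0+1, n1, n2), the two transverse components
``vq`` (n0, n1+1, n2) and ``wq`` (n0, n1, n2+1) are staggered along axes 1
and 2.  Face states: 0 solid (value pinned to 0), 1 active, 2 prescribed
(inlet), 4 outflow (top copy).  Wall-adjacent viscous stencils use the
face signed distance ``phif`` to place the no-slip plane at its sub-grid
position (ghost-distance Laplacian).
"""

import numba
import numpy as np

FACE_SOLID = 0
FACE_ACTIVE = 1
FACE_PRESCRIBED = 2
FACE_OUTFLOW = 4

CELL_SOLID = 0
CELL_FLUID = 1
CELL_INLET = 2
CELL_OUTLET = 3


@numba.njit(cache=True, fastmath=True)
def _upwind_derivative(um2, um1, u0, up1, up2, vel, h, has_m2, has_p2):
    """Second-order upwind derivative of the advected quantity at a face."""
    if vel >= 0.0:
        if has_m2:
            return (3.0 * u0 - 4.0 * um1 + um2) / (2.0 * h)
        return (u0 - um1) / h
    if has_p2:
        return (-3.0 * u0 + 4.0 * up1 - up2) / (2.0 * h)
    return (up1 - u0) / h


@numba.njit(cache=True, fastmath=True)
def momentum_rhs(u, vq, wq, st, phif, h, nu, out):
    """Explicit advection + ghost-distance diffusion for one component.

    Writes du/dt into ``out`` at active faces (0 elsewhere).
    """
    n0, n1, n2 = u.shape
    for i in range(1, n0 - 1):
        for j in range(n1):
            for k in range(n2):
                if st[i, j, k] != FACE_ACTIVE:
                    out[i, j, k] = 0.0
                    continue
                uc = u[i, j, k]
                vv = 0.25 * (
                    vq[i - 1, j, k] + vq[i - 1, j + 1, k]
                    + vq[i, j, k] + vq[i, j + 1, k]
                )
                ww = 0.25 * (
                    wq[i - 1, j, k] + wq[i - 1, j, k + 1]
                    + wq[i, j, k] + wq[i, j, k + 1]
                )
                # --- advection (2nd-order upwind, 1st near boundaries)
                um1 = u[i - 1, j, k]
                up1 = u[i + 1, j, k]
                um2 = u[i - 2, j, k] if i >= 2 else 0.0
                up2 = u[i + 2, j, k] if i + 2 <= n0 - 1 else 0.0
                dudx = _upwind_derivative(
                    um2, um1, uc, up1, up2, uc, h, i >= 2, i + 2 <= n0 - 1
                )
                jm1 = u[i, j - 1, k] if j >= 1 else 0.0
                jp1 = u[i, j + 1, k] if j + 1 <= n1 - 1 else 0.0
                jm2 = u[i, j - 2, k] if j >= 2 else 0.0
                jp2 = u[i, j + 2, k] if j + 2 <= n1 - 1 else 0.0
                dudy = _upwind_derivative(
                    jm2, jm1, uc, jp1, jp2, vv, h, j >= 2, j + 2 <= n1 - 1
                )
                km1 = u[i, j, k - 1] if k >= 1 else 0.0
                kp1 = u[i, j, k + 1] if k + 1 <= n2 - 1 else 0.0
                km2 = u[i, j, k - 2] if k >= 2 else 0.0
                kp2 = u[i, j, k + 2] if k + 2 <= n2 - 1 else 0.0
                dudz = _upwind_derivative(
                    km2, km1, uc, kp1, kp2, ww, h, k >= 2, k + 2 <= n2 - 1
                )
                adv = uc * dudx + vv * dudy + ww * dudz
                # --- diffusion with sub-grid wall distances
                lap = 0.0
                pf = phif[i, j, k]
                # axis 0
                a = h
                ua = um1
                if st[i - 1, j, k] == FACE_SOLID:
                    th = _theta(pf, phif[i - 1, j, k])
                    a = th * h
                    ua = 0.0
                b = h
                ub = up1
                if st[i + 1, j, k] == FACE_SOLID:
                    th = _theta(pf, phif[i + 1, j, k])
                    b = th * h
                    ub = 0.0
                lap += 2.0 * (ua / (a * (a + b)) - uc / (a * b) + ub / (b * (a + b)))
                # axis 1
                a = h
                ua = jm1
                if j >= 1:
                    if st[i, j - 1, k] == FACE_SOLID:
                        th = _theta(pf, phif[i, j - 1, k])
                        a = th * h
                        ua = 0.0
                else:
                    a = 0.5 * h
                    ua = 0.0
                b = h
                ub = jp1
                if j + 1 <= n1 - 1:
                    if st[i, j + 1, k] == FACE_SOLID:
                        th = _theta(pf, phif[i, j + 1, k])
                        b = th * h
                        ub = 0.0
                else:
                    b = 0.5 * h
                    ub = 0.0
                lap += 2.0 * (ua / (a * (a + b)) - uc / (a * b) + ub / (b * (a + b)))
                # axis 2
                a = h
                ua = km1
                if k >= 1:
                    if st[i, j, k - 1] == FACE_SOLID:
                        th = _theta(pf, phif[i, j, k - 1])
                        a = th * h
                        ua = 0.0
                else:
                    a = 0.5 * h
                    ua = 0.0
                b = h
                ub = kp1
                if k + 1 <= n2 - 1:
                    if st[i, j, k + 1] == FACE_SOLID:
                        th = _theta(pf, phif[i, j, k + 1])
                        b = th * h
                        ub = 0.0
                else:
                    b = 0.5 * h
                    ub = 0.0
                lap += 2.0 * (ua / (a * (a + b)) - uc / (a * b) + ub / (b * (a + b)))
                out[i, j, k] = -adv + nu * lap


@numba.njit(cache=True, fastmath=True)
def _theta(phi_f, phi_n):
    """Fractional distance from a fluid face to the wall along a grid line."""
    denom = phi_f - phi_n
    if denom >= -1e-30:  # no zero crossing resolved; fall back to full spacing
        return 1.0
    th = phi_f / denom
    if th < 0.1:
        return 0.1
    if th > 1.0:
        return 1.0
    return th


@numba.njit(cache=True, fastmath=True)
def divergence(u, v, w, cell_type, h, out):
    nx, ny, nz = cell_type.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if cell_type[i, j, k] == CELL_FLUID:
                    out[i, j, k] = (
                        u[i + 1, j, k] - u[i, j, k]
                        + v[i, j + 1, k] - v[i, j, k]
                        + w[i, j, k + 1] - w[i, j, k]
                    ) / h
                else:
                    out[i, j, k] = 0.0


@numba.njit(cache=True, fastmath=True)
def correct_u(u, st, pc, h, dt):
    n0, n1, n2 = u.shape
    for i in range(1, n0 - 1):
        for j in range(n1):
            for k in range(n2):
                if st[i, j, k] == FACE_ACTIVE:
                    u[i, j, k] -= dt * (pc[i, j, k] - pc[i - 1, j, k]) / h


@numba.njit(cache=True, fastmath=True)
def correct_v(v, st, pc, h, dt):
    n0, n1, n2 = v.shape
    for i in range(n0):
        for j in range(1, n1 - 1):
            for k in range(n2):
                if st[i, j, k] == FACE_ACTIVE:
                    v[i, j, k] -= dt * (pc[i, j, k] - pc[i, j - 1, k]) / h


@numba.njit(cache=True, fastmath=True)
def correct_w(w, st, pc, h, dt):
    n0, n1, n2 = w.shape
    for i in range(n0):
        for j in range(n1):
            for k in range(1, n2 - 1):
                if st[i, j, k] == FACE_ACTIVE:
                    w[i, j, k] -= dt * (pc[i, j, k] - pc[i, j, k - 1]) / h


@numba.njit(cache=True, fastmath=True)
def max_speed(u, v, w):
    m = 0.0
    for x in u.flat:
        if abs(x) > m:
            m = abs(x)
    for x in v.flat:
        if abs(x) > m:
            m = abs(x)
    for x in w.flat:
        if abs(x) > m:
            m = abs(x)
    return m
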