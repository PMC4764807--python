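"""Numba kernels for the explicit finite-difference update.

Everything here operates on plain float64 arrays so the hot loop compiles to
machine code once and is reused by every scenario.  The phase-field form of
the diffusion operator,

    (1/phi) div(phi (grad u - E)),

is evaluated in flux form with face-averaged phi, which reduces exactly to
the 7-point Laplacian where phi == 1 and enforces n.grad(u) = n.E across the
smoothed obstacle interface.  The domain boundary is no-flux via mirrored
ghost nodes (u[-1] := u[1]).  Obstacle-interior nodes (phi below the floor)
are held at rest: their update is multiplied by the 0/1 activity mask, and
flux out of them is suppressed because 1/phi is stored as zero there.

The inner loop is branch-free so LLVM can vectorize it; buffers are
ping-ponged between steps instead of copied.
"""

from __future__ import annotations

import numba
import numpy as np

# field kind codes shared with fields.FieldSpec
KIND_NONE, KIND_PDCEF, KIND_ACEF, KIND_CPEF = 0, 1, 2, 3

TWO_PI = 2.0 * np.pi


@numba.njit(cache=True, inline="always")
def _field_at(kind, E0, omega, d, phase, t):
    ex = 0.0
    ey = 0.0
    if kind == KIND_PDCEF:
        tp = t % (TWO_PI / omega)
        if tp < d:
            ex = E0
    elif kind == KIND_ACEF:
        ex = E0 * np.cos(omega * t + phase)
    elif kind == KIND_CPEF:
        wt = omega * t + phase
        ex = E0 * np.cos(wt)
        ey = E0 * np.sin(wt)
    return ex, ey


@numba.njit(cache=True, fastmath=True)
def _step(u, v, un, vn, phi, inv_phi, act, tissue, fx, fy,
          a, b, eps, dx, dt, ex, ey, v_lo, v_hi):
    nx, ny, nz = u.shape
    hdx2 = 0.5 / (dx * dx)
    inv_eps = 1.0 / eps
    inv_a = 1.0 / a
    for i in range(nx):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < nx - 1 else nx - 2
        for j in range(ny):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < ny - 1 else ny - 2
            for k in range(1, nz - 1):
                u0 = u[i, j, k]
                v0 = v[i, j, k]
                p0 = phi[i, j, k]
                flux = (
                    (p0 + phi[ip, j, k]) * (u[ip, j, k] - u0)
                    + (p0 + phi[im, j, k]) * (u[im, j, k] - u0)
                    + (p0 + phi[i, jp, k]) * (u[i, jp, k] - u0)
                    + (p0 + phi[i, jm, k]) * (u[i, jm, k] - u0)
                    + (p0 + phi[i, j, k + 1]) * (u[i, j, k + 1] - u0)
                    + (p0 + phi[i, j, k - 1]) * (u[i, j, k - 1] - u0)
                )
                react = inv_eps * u0 * (1.0 - u0) * (u0 - (v0 + b) * inv_a)
                force = fx[i, j, k] * ex + fy[i, j, k] * ey
                rm = tissue[i, j, k]
                un[i, j, k] = act[i, j, k] * (
                    u0 + dt * (rm * react + flux * hdx2 * inv_phi[i, j, k] + force)
                )
                vnew = act[i, j, k] * (v0 + dt * rm * (u0 - v0))
                vn[i, j, k] = min(max(vnew, v_lo), v_hi)
            # the two z-boundary sheets, with mirrored ghosts
            for k in (0, nz - 1):
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < nz - 1 else nz - 2
                u0 = u[i, j, k]
                v0 = v[i, j, k]
                p0 = phi[i, j, k]
                flux = (
                    (p0 + phi[ip, j, k]) * (u[ip, j, k] - u0)
                    + (p0 + phi[im, j, k]) * (u[im, j, k] - u0)
                    + (p0 + phi[i, jp, k]) * (u[i, jp, k] - u0)
                    + (p0 + phi[i, jm, k]) * (u[i, jm, k] - u0)
                    + (p0 + phi[i, j, kp]) * (u[i, j, kp] - u0)
                    + (p0 + phi[i, j, km]) * (u[i, j, km] - u0)
                )
                react = inv_eps * u0 * (1.0 - u0) * (u0 - (v0 + b) * inv_a)
                force = fx[i, j, k] * ex + fy[i, j, k] * ey
                rm = tissue[i, j, k]
                un[i, j, k] = act[i, j, k] * (
                    u0 + dt * (rm * react + flux * hdx2 * inv_phi[i, j, k] + force)
                )
                vnew = act[i, j, k] * (v0 + dt * rm * (u0 - v0))
                vn[i, j, k] = min(max(vnew, v_lo), v_hi)


@numba.njit(cache=True)
def advance(u, v, un, vn, phi, inv_phi, act, tissue, fx, fy,
            a, b, eps, dx, dt, t0, nsteps, kind, E0, omega, d, phase,
            v_lo, v_hi):
    """Advance (u, v) by ``nsteps`` forward-Euler steps from t0.

    ``un, vn`` are scratch buffers of the same shape.  The result is always
    left in ``u, v``; returns the final time t0 + nsteps*dt.
    """
    cu, cv, nu, nv = u, v, un, vn
    for step in range(nsteps):
        t = t0 + step * dt
        ex, ey = _field_at(kind, E0, omega, d, phase, t)
        _step(cu, cv, nu, nv, phi, inv_phi, act, tissue, fx, fy,
              a, b, eps, dx, dt, ex, ey, v_lo, v_hi)
        cu, nu = nu, cu
        cv, nv = nv, cv
    if nsteps % 2 == 1:
        u[:, :, :] = cu
        v[:, :, :] = cv
    return t0 + nsteps * dt


@numba.njit(cache=True)
def rate_kernel(u, phi, inv_phi, fx, fy, fz, dx, ex, ey, ez, out):
    """Diffusion plus field forcing rate: (1/phi) div(phi grad u) + forcing.

    ``fx, fy, fz`` hold the precomputed forcing direction -(grad phi)/phi
    (zero on inactive nodes); ``inv_phi`` is 1/phi on active nodes and 0 on
    obstacle-interior nodes, which also serves as the mask.
    """
    nx, ny, nz = u.shape
    hdx2 = 0.5 / (dx * dx)
    for i in range(nx):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < nx - 1 else nx - 2
        for j in range(ny):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < ny - 1 else ny - 2
            for k in range(nz):
                if inv_phi[i, j, k] == 0.0:
                    out[i, j, k] = 0.0
                    continue
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < nz - 1 else nz - 2
                u0 = u[i, j, k]
                p0 = phi[i, j, k]
                flux = (
                    (p0 + phi[ip, j, k]) * (u[ip, j, k] - u0)
                    + (p0 + phi[im, j, k]) * (u[im, j, k] - u0)
                    + (p0 + phi[i, jp, k]) * (u[i, jp, k] - u0)
                    + (p0 + phi[i, jm, k]) * (u[i, jm, k] - u0)
                    + (p0 + phi[i, j, kp]) * (u[i, j, kp] - u0)
                    + (p0 + phi[i, j, km]) * (u[i, j, km] - u0)
                )
                out[i, j, k] = flux * hdx2 * inv_phi[i, j, k] + (
                    fx[i, j, k] * ex + fy[i, j, k] * ey + fz[i, j, k] * ez
                )
    return out
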