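"""Independent ghost-node Neumann reference solvers.

Small explicit finite-difference solvers for diffusion with linear decay
and a flux boundary condition du/dn = E at an obstacle surface, written
directly on body-fitted grids (no phase field).  They serve as oracles for
the phase-field boundary treatment: both discretize the same continuum
problem, so their steady profiles must agree.
"""

from __future__ import annotations

import numpy as np


def disk_ghost_node(
    E0: float, k: float, R: float, h: float, r_max: float, t_end: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """cos(phi) mode around a 2D disk obstacle of radius R.

    With u(r, phi) = w(r) cos(phi), solves
    w_t = w'' + w'/r - w/r^2 - k w on [R, r_max] with w'(R) = E0 (the
    du/dn = E0 cos(phi) condition) via an inner ghost node, and w = 0 at
    the far end.  Returns (r, w) at t_end.
    """
    n = int(round((r_max - R) / h)) + 1
    r = R + np.arange(n) * h
    w = np.zeros(n)
    steps = int(round(t_end / dt))
    for _ in range(steps):
        ghost = w[1] - 2.0 * h * E0
        wm = np.concatenate(([ghost], w[:-1]))
        wp = np.concatenate((w[1:], [0.0]))
        lap = (wp - 2 * w + wm) / h**2 + (wp - wm) / (2 * h * r) - w / r**2
        w = w + dt * (lap - k * w)
        w[-1] = 0.0
    return r, w
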