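"""Wave and filament analysis: probe frequencies, filament detection,
removal classification.

The scroll-wave filament is located as the intersection curve of the two
isosurfaces u = u_iso and v = v_iso.  On every grid-cell face where both
isolines cross, their bilinear intersection point is found by a 2D Newton
solve; the resulting point cloud samples the filament to sub-cell accuracy.
Activation frequencies are measured from the times at which u rises through
a threshold at fixed probe points, as one would from an electrode recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numba
import numpy as np

from .model import MediumState, PhaseFieldDomain
from .params import ModelParams

DEFAULT_U_ISO = 0.5


def default_v_iso(params: ModelParams) -> float:
    """Mid-range recovery isovalue a/2 - b (0.37 at default kinetics)."""
    return params.a / 2.0 - params.b


# --------------------------------------------------------------------------
# probes


@dataclass
class ProbeSeries:
    """u(t) sampled at a fixed grid point with uniform cadence."""

    position: tuple[float, float, float]
    times: np.ndarray
    u_values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.u_values = np.asarray(self.u_values, float)
        if self.times.size != self.u_values.size:
            raise ValueError("times and u_values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


class InsufficientActivationsError(ValueError):
    """Too few threshold crossings to estimate a frequency."""


def upward_crossings(series: ProbeSeries, threshold: float) -> np.ndarray:
    """Times at which u rises through the threshold (linear interpolation)."""
    u = series.u_values
    t = series.times
    below = u[:-1] < threshold
    above = u[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - u[idx]) / (u[idx + 1] - u[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def activation_frequency(
    series: ProbeSeries, threshold: float = DEFAULT_U_ISO, discard: int = 2
) -> tuple[float, float]:
    """Angular frequency 2*pi / mean inter-activation interval, plus the
    coefficient of variation of the intervals.

    The first ``discard`` crossings are dropped as start-up transient; at
    least 4 crossings must remain.
    """
    crossings = upward_crossings(series, threshold)[discard:]
    if crossings.size < 4:
        raise InsufficientActivationsError(
            f"need >= 4 usable activations, found {crossings.size}"
        )
    intervals = np.diff(crossings)
    mean = float(intervals.mean())
    cv = float(intervals.std() / mean)
    return 2.0 * np.pi / mean, cv


# --------------------------------------------------------------------------
# filament detection


@numba.njit(cache=True, inline="always")
def _face_newton(f00, f10, f01, f11, g00, g10, g01, g11):
    """Intersection of the bilinear isolines f=0 and g=0 on a unit face.

    Returns (s, t, ok)."""
    a0, a1, a2, a3 = f00, f10 - f00, f01 - f00, f11 - f10 - f01 + f00
    b0, b1, b2, b3 = g00, g10 - g00, g01 - g00, g11 - g10 - g01 + g00
    s = 0.5
    t = 0.5
    for _ in range(16):
        f = a0 + a1 * s + a2 * t + a3 * s * t
        g = b0 + b1 * s + b2 * t + b3 * s * t
        j11 = a1 + a3 * t
        j12 = a2 + a3 * s
        j21 = b1 + b3 * t
        j22 = b2 + b3 * s
        det = j11 * j22 - j12 * j21
        if abs(det) < 1e-14:
            return 0.0, 0.0, False
        ds = (f * j22 - g * j12) / det
        dtt = (g * j11 - f * j21) / det
        s -= ds
        t -= dtt
        if abs(ds) + abs(dtt) < 1e-10:
            break
    f = a0 + a1 * s + a2 * t + a3 * s * t
    g = b0 + b1 * s + b2 * t + b3 * s * t
    ok = (-1e-9 <= s <= 1.0 + 1e-9) and (-1e-9 <= t <= 1.0 + 1e-9) and (
        abs(f) < 1e-8 and abs(g) < 1e-8
    )
    return s, t, ok


@numba.njit(cache=True)
def _filament_kernel(u, v, phi, u_iso, v_iso, dx, out):
    """Scan all cell faces for simultaneous u- and v-isoline crossings."""
    nx, ny, nz = u.shape
    cap = out.shape[0]
    n = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                # three face orientations with lower corner (i, j, k)
                for ax in range(3):
                    if ax == 0:  # face in the yz-plane? no: normal x -> spanned by y,z
                        if j + 1 >= ny or k + 1 >= nz:
                            continue
                        i1, j1, k1 = i, j + 1, k
                        i2, j2, k2 = i, j, k + 1
                        i3, j3, k3 = i, j + 1, k + 1
                    elif ax == 1:  # normal y -> spanned by x,z
                        if i + 1 >= nx or k + 1 >= nz:
                            continue
                        i1, j1, k1 = i + 1, j, k
                        i2, j2, k2 = i, j, k + 1
                        i3, j3, k3 = i + 1, j, k + 1
                    else:  # normal z -> spanned by x,y
                        if i + 1 >= nx or j + 1 >= ny:
                            continue
                        i1, j1, k1 = i + 1, j, k
                        i2, j2, k2 = i, j + 1, k
                        i3, j3, k3 = i + 1, j + 1, k
                    if (
                        phi[i, j, k] < 0.5
                        or phi[i1, j1, k1] < 0.5
                        or phi[i2, j2, k2] < 0.5
                        or phi[i3, j3, k3] < 0.5
                    ):
                        continue
                    f00 = u[i, j, k] - u_iso
                    f10 = u[i1, j1, k1] - u_iso
                    f01 = u[i2, j2, k2] - u_iso
                    f11 = u[i3, j3, k3] - u_iso
                    if (f00 > 0 and f10 > 0 and f01 > 0 and f11 > 0) or (
                        f00 < 0 and f10 < 0 and f01 < 0 and f11 < 0
                    ):
                        continue
                    g00 = v[i, j, k] - v_iso
                    g10 = v[i1, j1, k1] - v_iso
                    g01 = v[i2, j2, k2] - v_iso
                    g11 = v[i3, j3, k3] - v_iso
                    if (g00 > 0 and g10 > 0 and g01 > 0 and g11 > 0) or (
                        g00 < 0 and g10 < 0 and g01 < 0 and g11 < 0
                    ):
                        continue
                    s, t, ok = _face_newton(f00, f10, f01, f11, g00, g10, g01, g11)
                    if not ok or n >= cap:
                        continue
                    if ax == 0:
                        out[n, 0] = i * dx
                        out[n, 1] = (j + s) * dx
                        out[n, 2] = (k + t) * dx
                    elif ax == 1:
                        out[n, 0] = (i + s) * dx
                        out[n, 1] = j * dx
                        out[n, 2] = (k + t) * dx
                    else:
                        out[n, 0] = (i + s) * dx
                        out[n, 1] = (j + t) * dx
                        out[n, 2] = k * dx
                    n += 1
    return n


def detect_filament(
    state: MediumState,
    domain: PhaseFieldDomain,
    params: ModelParams,
    u_iso: float = DEFAULT_U_ISO,
    v_iso: float | None = None,
) -> np.ndarray:
    """Filament point cloud (N, 3) in physical coordinates.

    Empty when no scroll wave is present.  Faces with any corner inside the
    obstacle (phi < 0.5) are excluded.
    """
    if v_iso is None:
        v_iso = default_v_iso(params)
    out = np.empty((100_000, 3))
    n = _filament_kernel(state.u, state.v, domain.phi, u_iso, v_iso, params.dx, out)
    return out[:n].copy()


# --------------------------------------------------------------------------
# traces and removal classification


@dataclass
class FilamentTrace:
    """Filament point sets sampled over time, with the geometry needed to
    derive distances to the obstacle and to the success box."""

    center: tuple[float, float, float]
    radius: float
    dx: float
    times: list[float] = dc_field(default_factory=list)
    points: list[np.ndarray] = dc_field(default_factory=list)

    def append(self, t: float, pts: np.ndarray) -> None:
        self.times.append(float(t))
        self.points.append(np.asarray(pts, float).reshape(-1, 3))

    def surface_distances(self) -> list[float]:
        """Per sample: min distance from filament to the obstacle surface
        (inf when the filament is absent)."""
        out = []
        c = np.asarray(self.center)
        for pts in self.points:
            if len(pts) == 0:
                out.append(np.inf)
            else:
                d = np.abs(np.linalg.norm(pts - c, axis=1) - self.radius)
                out.append(float(d.min()))
        return out

    def points_in_box(self, half_width: float) -> list[int]:
        """Per sample: number of filament points inside the obstacle-centered
        cube of the given half-width."""
        c = np.asarray(self.center)
        out = []
        for pts in self.points:
            if len(pts) == 0:
                out.append(0)
            else:
                inside = np.all(np.abs(pts - c) <= half_width, axis=1)
                out.append(int(inside.sum()))
        return out

    def to_frame(self):
        """Long-format table (time, x, y, z) of all filament points."""
        import pandas as pd

        rows = []
        for t, pts in zip(self.times, self.points):
            for p in pts:
                rows.append((t, p[0], p[1], p[2]))
        return pd.DataFrame(rows, columns=["time", "x", "y", "z"])


@dataclass
class RemovalOutcome:
    """Removal classification of one driven run.

    t_detach: filament first clear of the obstacle surface (> 1 dx).
    t_removed: filament first entirely outside the success box.
    t_swept: filament point set first empty anywhere in the medium.
    success: removed (box criterion) within t_limit.
    """

    success: bool
    t_detach: float | None
    t_removed: float | None
    box_half_width: float
    t_limit: float
    t_swept: float | None = None
    final_quiescent: bool | None = None

    def to_dict(self) -> dict:
        opt = lambda v: None if v is None else float(v)
        return {
            "success": bool(self.success),
            "t_detach": opt(self.t_detach),
            "t_removed": opt(self.t_removed),
            "t_swept": opt(self.t_swept),
            "final_quiescent": self.final_quiescent,
            "box_half_width": float(self.box_half_width),
            "t_limit": float(self.t_limit),
        }


def classify_removal(
    trace: FilamentTrace, box_half_width: float, t_limit: float = 500.0
) -> RemovalOutcome:
    """Detachment and removal times from a filament trace.

    t_detach: first sample with no filament point within one grid spacing of
    the obstacle surface.  t_removed: first sample with no filament point
    inside the obstacle-centered box.  success: removed within t_limit.
    """
    if len(trace.times) == 0:
        raise ValueError("empty filament trace")
    t_detach = None
    for t, d in zip(trace.times, trace.surface_distances()):
        if d > trace.dx:
            t_detach = t
            break
    t_removed = None
    for t, n_in in zip(trace.times, trace.points_in_box(box_half_width)):
        if n_in == 0:
            t_removed = t
            break
    t_swept = None
    for t, pts in zip(trace.times, trace.points):
        if len(pts) == 0:
            t_swept = t
            break
    success = t_removed is not None and t_removed <= t_limit
    return RemovalOutcome(success, t_detach, t_removed, box_half_width, t_limit,
                          t_swept=t_swept)


def is_quiescent(
    state: MediumState, domain: PhaseFieldDomain, tol: float = 0.01
) -> bool:
    """True iff max u over tissue nodes (phi >= 0.5) is below ``tol``."""
    tissue = domain.phi >= 0.5
    return bool(np.max(np.where(tissue, state.u, 0.0)) < tol)
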