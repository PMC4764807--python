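"""Snapshot containers, trace tables and VTK export.

Snapshots are single HDF5 files holding u, v, phi and the simulation time
plus enough metadata to rebuild the grid.  Filament traces and probe series
go to CSV; run outcomes to JSON.  For 3D visualization a minimal legacy
ASCII VTK structured-points writer is provided (readable by ParaView).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .model import MediumState, PhaseFieldDomain
from .params import ModelParams


def save_snapshot(
    path: str | Path,
    state: MediumState,
    domain: PhaseFieldDomain,
    params: ModelParams,
) -> None:
    """Write u, v, phi, time and grid metadata to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=state.u, compression="gzip", compression_opts=4)
        f.create_dataset("v", data=state.v, compression="gzip", compression_opts=4)
        f.create_dataset("phi", data=domain.phi, compression="gzip", compression_opts=4)
        f.attrs["t"] = state.t
        f.attrs["dx"] = params.dx
        f.attrs["dt"] = params.dt
        f.attrs["a"] = params.a
        f.attrs["b"] = params.b
        f.attrs["epsilon"] = params.epsilon
        f.attrs["phi_floor"] = params.phi_floor
        f.attrs["obstacle_center"] = domain.center
        f.attrs["obstacle_radius"] = domain.radius
        f.attrs["interface_width"] = domain.interface_width


def load_snapshot(path: str | Path) -> tuple[MediumState, PhaseFieldDomain, ModelParams]:
    """Inverse of :func:`save_snapshot`."""
    with h5py.File(path, "r") as f:
        u = f["u"][...]
        v = f["v"][...]
        phi = f["phi"][...]
        at = dict(f.attrs)
    params = ModelParams(
        a=float(at["a"]),
        b=float(at["b"]),
        epsilon=float(at["epsilon"]),
        dx=float(at["dx"]),
        dt=float(at["dt"]),
        grid_shape=tuple(u.shape),
        phi_floor=float(at["phi_floor"]),
    )
    domain = PhaseFieldDomain(
        phi=phi,
        center=tuple(float(c) for c in at["obstacle_center"]),
        radius=float(at["obstacle_radius"]),
        interface_width=float(at["interface_width"]),
        phi_floor=params.phi_floor,
    )
    domain.finalize_gradient(params.dx)
    return MediumState(u=u, v=v, t=float(at["t"])), domain, params


def write_vtk(
    path: str | Path,
    params: ModelParams,
    **fields: np.ndarray,
) -> None:
    """Legacy ASCII VTK structured-points file with the given scalar fields
    as point data (for ParaView/VisIt rendering)."""
    if not fields:
        raise ValueError("at least one field required")
    shapes = {f.shape for f in fields.values()}
    if len(shapes) != 1 or shapes.pop() != tuple(params.grid_shape):
        raise ValueError("all fields must match the grid shape")
    nx, ny, nz = params.grid_shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nscrollwave snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {params.dx} {params.dx} {params.dx}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK structured points vary x fastest
            flat = np.asarray(arr, np.float32).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.5g")


def write_outcome(path: str | Path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, default=float) + "\n")
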