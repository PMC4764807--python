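"""YAML run configuration.

Sections (all optional, all keys defaulted):

    model:    {a, b, epsilon, dx, dt, grid}
    obstacle: {radius, center, interface_width}
    field:    {kind, E0, omega_e, pulse_duration}
    run:      {t_end, snapshot_every, probe_offset, t_limit, box_half_width}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .fields import FieldKind, FieldSpec
from .model import PhaseFieldDomain, build_phase_field
from .params import ModelParams, stable_dt


@dataclass(frozen=True)
class RunSettings:
    t_end: float = 40.0
    snapshot_every: float | None = None
    probe_offset: float | None = None
    t_limit: float = 500.0
    box_half_width: float | None = None


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    obstacle_radius: float
    obstacle_center: tuple[float, float, float] | None
    interface_width: float | None
    field: FieldSpec
    run: RunSettings

    def domain(self) -> PhaseFieldDomain:
        center = self.obstacle_center or self.params.center
        xi = self.interface_width or 2 * self.params.dx
        return build_phase_field(center, self.obstacle_radius, xi, self.params)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus flat override dict.

    Override keys use dotted paths, e.g. {"field.E0": 2.0, "model.grid": 60}.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        sect, _, name = key.partition(".")
        raw.setdefault(sect, {})[name] = val

    m = raw.get("model", {})
    grid = m.get("grid", 60)
    if isinstance(grid, int):
        grid = (grid, grid, grid)
    dx = float(m.get("dx", 0.25))
    params = ModelParams(
        a=float(m.get("a", 0.9)),
        b=float(m.get("b", 0.08)),
        epsilon=float(m.get("epsilon", 0.02)),
        dx=dx,
        dt=float(m.get("dt", stable_dt(dx))),
        grid_shape=tuple(int(g) for g in grid),
        phi_floor=float(m.get("phi_floor", 0.05)),
    )

    o = raw.get("obstacle", {})
    center = o.get("center")
    if center is not None:
        center = tuple(float(c) for c in center)

    f = raw.get("field", {})
    field = FieldSpec(
        kind=FieldKind(str(f.get("kind", "none")).lower()),
        E0=float(f.get("E0", 0.0)),
        omega_e=float(f.get("omega_e", 1.0)),
        pulse_duration=float(f.get("pulse_duration", 0.0)),
    )

    r = raw.get("run", {})
    run = RunSettings(
        t_end=float(r.get("t_end", 40.0)),
        snapshot_every=(None if r.get("snapshot_every") is None
                        else float(r["snapshot_every"])),
        probe_offset=(None if r.get("probe_offset") is None
                      else float(r["probe_offset"])),
        t_limit=float(r.get("t_limit", 500.0)),
        box_half_width=(None if r.get("box_half_width") is None
                        else float(r["box_half_width"])),
    )

    return RunConfig(
        params=params,
        obstacle_radius=float(o.get("radius", 3.0)),
        obstacle_center=center,
        interface_width=(None if o.get("interface_width") is None
                         else float(o["interface_width"])),
        field=field,
        run=run,
    )
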