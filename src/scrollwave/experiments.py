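"""Scenario runners: wave emission from the obstacle, frequency scans,
pinned-scroll removal, and the (E0, omega_e) phase diagram.

The central comparison in every scenario is between omega_wave -- the
angular frequency of the spherical waves the field nucleates at the
obstacle in an otherwise quiescent medium -- and omega_scroll, the rotation
frequency of the scroll wave pinned to the same obstacle.  Only waves
faster than the pinned scroll can invade its territory and push the
filament off the obstacle and out of the medium.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import (
    FilamentTrace,
    InsufficientActivationsError,
    ProbeSeries,
    RemovalOutcome,
    activation_frequency,
    classify_removal,
    detect_filament,
    is_quiescent,
    upward_crossings,
)
from .fields import FieldKind, FieldSpec
from .initial import quiescent_state
from .model import MediumState, PhaseFieldDomain, integrate
from .params import ModelParams

PROBE_SAMPLE_INTERVAL = 0.05  # time units between probe samples
TRACE_SAMPLE_INTERVAL = 1.0  # time units between filament samples


def removal_reference_setup(radius: float = 3.0):
    """Reference geometry for the unpinning scenarios: a laterally
    elongated box (120 x 120 x 60 nodes, 30 x 30 x 15 space units) with the
    obstacle at the center.

    The lateral room matters: near a no-flux wall a filament interacts with
    its mirror image, and in a cubic box whose wall sits within about half
    a scroll wavelength of the obstacle the driven filament is annihilated
    at the wall apex-first and re-pins instead of being swept out.

    Returns (params, domain).
    """
    from .model import build_phase_field
    from .params import ModelParams

    params = ModelParams(grid_shape=(120, 120, 60))
    domain = build_phase_field(params.center, radius, 4 * params.dx, params)
    return params, domain


# --------------------------------------------------------------------------
# probes


def axis_probe_positions(
    domain: PhaseFieldDomain, params: ModelParams, offset: float | None = None
) -> list[tuple[int, int, int]]:
    """Grid indices of six probes, one along each +-axis direction at
    ``offset`` (default 10 dx) outside the obstacle surface.

    The default offset shrinks to fit small boxes; an explicit offset that
    falls outside the grid is an error."""
    if offset is None:
        margin = min(
            min(c, ln - c) for c, ln in zip(domain.center, params.box_lengths)
        )
        offset = min(10 * params.dx, margin - domain.radius - 2 * params.dx)
        if offset <= 0:
            raise ValueError("no room for probes outside the obstacle")
    d = domain.radius + offset
    c = np.asarray(domain.center)
    out = []
    for ax in range(3):
        for sign in (+1, -1):
            p = c.copy()
            p[ax] += sign * d
            idx = tuple(int(round(cc / params.dx)) for cc in p)
            for n, i in zip(params.grid_shape, idx):
                if not (0 <= i < n):
                    raise ValueError("probe outside the grid; reduce offset")
            out.append(idx)
    return out


class _ProbeRecorder:
    """Observer collecting u at fixed grid indices."""

    def __init__(self, positions: Sequence[tuple[int, int, int]], dx: float):
        self.positions = list(positions)
        self.dx = dx
        self.times: list[float] = []
        self.values: list[list[float]] = [[] for _ in self.positions]

    def __call__(self, state: MediumState) -> None:
        self.times.append(state.t)
        for buf, idx in zip(self.values, self.positions):
            buf.append(float(state.u[idx]))

    def series(self, i: int) -> ProbeSeries:
        pos = tuple(c * self.dx for c in self.positions[i])
        return ProbeSeries(pos, np.asarray(self.times), np.asarray(self.values[i]))


def measure_scroll_frequency(
    state: MediumState,
    domain: PhaseFieldDomain,
    params: ModelParams,
    duration: float = 25.0,
) -> tuple[float, float]:
    """Rotation frequency of a (pinned) scroll from two probes at
    perpendicular azimuths; returns (omega, interval CV).  The input state
    is not modified."""
    work = state.copy()
    rec = _ProbeRecorder(axis_probe_positions(domain, params)[:4:2], params.dx)
    # probes 0 and 2 are +x and +y: perpendicular azimuths
    integrate(work, domain, FieldSpec.none(), params, work.t + duration,
              observers=[(PROBE_SAMPLE_INTERVAL, rec)])
    omegas, cvs = [], []
    for i in range(2):
        w, cv = activation_frequency(rec.series(i))
        omegas.append(w)
        cvs.append(cv)
    return float(np.mean(omegas)), float(np.mean(cvs))


# --------------------------------------------------------------------------
# scan bookkeeping


def _config_hash(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclass
class ScanResult:
    """Tabular result of a parameter scan with full provenance."""

    table: pd.DataFrame
    omega_scroll: float | None
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.metadata.setdefault("config_hash", _config_hash(self.metadata))


# --------------------------------------------------------------------------
# scenario runners


@dataclass
class WehOutcome:
    emitted: bool
    sound: bool
    omega_wave: float | None
    cv: float | None
    activations_per_probe: list[int]


def run_weh_quiescent(
    field: FieldSpec,
    params: ModelParams,
    domain: PhaseFieldDomain,
    t_end: float = 40.0,
    probe_offset: float | None = None,
) -> WehOutcome:
    """Apply a field to the quiescent medium and classify wave emission.

    emitted: at least 3 activations at the +x probe.  sound: a regular,
    unbroken spherical wave train -- interval CV below 10% on the
    measurement probes and all six axis probes activate on every cycle
    (equal crossing counts up to an edge effect of one).
    """
    state = quiescent_state(params)
    rec = _ProbeRecorder(axis_probe_positions(domain, params, probe_offset), params.dx)
    integrate(state, domain, field, params, t_end,
              observers=[(PROBE_SAMPLE_INTERVAL, rec)])
    counts = [len(upward_crossings(rec.series(i), 0.5)) for i in range(6)]
    emitted = counts[0] >= 3
    omega = cv = None
    sound = False
    if emitted:
        try:
            o1, c1 = activation_frequency(rec.series(0))
            o2, c2 = activation_frequency(rec.series(2))
            omega = float(np.mean([o1, o2]))
            cv = float(np.mean([c1, c2]))
            sound = cv < 0.10 and (min(counts) >= max(counts) - 1) and min(counts) >= 3
        except InsufficientActivationsError:
            pass
    return WehOutcome(emitted, sound, omega, cv, counts)


def run_frequency_scan(
    field_kind: FieldKind,
    E0: float,
    omega_list: Sequence[float],
    params: ModelParams,
    domain: PhaseFieldDomain,
    pulse_duration: float = 0.1,
    omega_scroll: float | None = None,
    t_end: float = 40.0,
    probe_offset: float | None = None,
) -> ScanResult:
    """omega_wave in the quiescent medium for each field frequency.

    Non-sound (broken or irregular) wave trains are recorded with
    ``sound=False`` rather than dropped.  When ``omega_scroll`` is given,
    each row carries the flag omega_wave > omega_scroll.
    """
    rows = []
    for we in omega_list:
        if field_kind is FieldKind.PDCEF:
            spec = FieldSpec.pdcef(E0, we, pulse_duration)
        elif field_kind is FieldKind.ACEF:
            spec = FieldSpec.acef(E0, we)
        elif field_kind is FieldKind.CPEF:
            spec = FieldSpec.cpef(E0, we)
        else:
            raise ValueError("scan requires a real field kind")
        out = run_weh_quiescent(spec, params, domain, t_end=t_end,
                                probe_offset=probe_offset)
        rows.append(
            {
                "omega_e": float(we),
                "emitted": out.emitted,
                "sound": out.sound,
                "omega_wave": np.nan if out.omega_wave is None else out.omega_wave,
                "cv": np.nan if out.cv is None else out.cv,
                "exceeds_scroll": (
                    bool(out.omega_wave is not None
                         and omega_scroll is not None
                         and out.omega_wave > omega_scroll)
                ),
            }
        )
    meta = {
        "kind": field_kind.value,
        "E0": E0,
        "pulse_duration": pulse_duration,
        "grid": params.grid_shape,
        "dx": params.dx,
        "dt": params.dt,
        "R": domain.radius,
        "t_end": t_end,
    }
    return ScanResult(pd.DataFrame(rows), omega_scroll, meta)


def run_removal(
    field: FieldSpec,
    params: ModelParams,
    domain: PhaseFieldDomain,
    pinned_state: MediumState,
    t_limit: float = 500.0,
    box_half_width: float | None = None,
    stop_on: str = "swept",
    quiescence_wait: float = 150.0,
) -> tuple[RemovalOutcome, FilamentTrace, MediumState]:
    """Drive a pinned scroll with the field and classify its removal.

    The field stays on until the stop event or ``t_limit``:
    ``stop_on="box"`` stops as soon as the filament leaves the
    obstacle-centered success box (the phase-diagram success criterion,
    allowing early termination of scan cells); ``stop_on="swept"`` keeps
    driving until no filament point remains anywhere in the medium (the
    complete sweep-out).  The field is then switched off and the run
    continues for up to ``quiescence_wait`` time units so the remaining
    target waves can leave through the boundary; ``final_quiescent``
    reports whether the medium reached the rest state.

    Returns (outcome, filament trace, final state).
    """
    if stop_on not in ("box", "swept"):
        raise ValueError("stop_on must be 'box' or 'swept'")
    if box_half_width is None:
        box_half_width = 2.0 * domain.radius
    state = pinned_state.copy()
    t0 = state.t
    trace = FilamentTrace(domain.center, domain.radius, params.dx)
    # the field waveform is referenced to onset time
    spec = FieldSpec(field.kind, field.E0, field.omega_e, field.pulse_duration,
                     phase=field.phase - field.omega_e * t0
                     if field.kind is not FieldKind.NONE else 0.0)
    pts = detect_filament(state, domain, params)
    trace.append(0.0, pts)
    center = np.asarray(domain.center)
    while state.t - t0 < t_limit - 1e-9:
        integrate(state, domain, spec, params, state.t + TRACE_SAMPLE_INTERVAL)
        pts = detect_filament(state, domain, params)
        trace.append(state.t - t0, pts)
        if len(pts) == 0:
            break
        if stop_on == "box" and not np.any(
            np.all(np.abs(pts - center) <= box_half_width, axis=1)
        ):
            break
    # field off; keep sampling the filament while the remaining target
    # waves leave through the boundary and any leftover fragments collapse
    end = state.t + quiescence_wait
    while state.t < end - 1e-9 and not is_quiescent(state, domain):
        integrate(state, domain, FieldSpec.none(), params, state.t + 2.0)
        trace.append(state.t - t0, detect_filament(state, domain, params))
    outcome = classify_removal(trace, box_half_width, t_limit)
    outcome.final_quiescent = is_quiescent(state, domain)
    return outcome, trace, state


def run_phase_diagram(
    E0_list: Sequence[float],
    omega_list: Sequence[float],
    params: ModelParams,
    domain: PhaseFieldDomain,
    pinned_state: MediumState,
    t_limit: float = 500.0,
    box_half_width: float | None = None,
) -> ScanResult:
    """Success/failure of CPEF removal over an (E0, omega_e) grid.

    The pinned reference state is reused (copied) for every cell; each
    removal run terminates as soon as success is classified.  The summary
    column ``n_success`` counts successful omega_e cells per E0 row.
    """
    rows = []
    for E0 in E0_list:
        for we in omega_list:
            spec = FieldSpec.cpef(E0, we) if E0 > 0 else FieldSpec.none()
            try:
                outcome, _trace, _ = run_removal(
                    spec, params, domain, pinned_state,
                    t_limit=t_limit, box_half_width=box_half_width,
                    stop_on="box", quiescence_wait=0.0,
                )
                rows.append(
                    {
                        "E0": float(E0),
                        "omega_e": float(we),
                        "success": outcome.success,
                        "t_detach": outcome.t_detach,
                        "t_removed": outcome.t_removed,
                        "error": "",
                    }
                )
            except Exception as exc:  # record per-cell failure, keep scanning
                rows.append(
                    {
                        "E0": float(E0),
                        "omega_e": float(we),
                        "success": False,
                        "t_detach": None,
                        "t_removed": None,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
    table = pd.DataFrame(rows)
    meta = {
        "grid": params.grid_shape,
        "dx": params.dx,
        "dt": params.dt,
        "R": domain.radius,
        "t_limit": t_limit,
        "box_half_width": box_half_width or 2.0 * domain.radius,
    }
    return ScanResult(table, None, meta)
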