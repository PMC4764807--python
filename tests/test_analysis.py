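"""Probe frequency estimation, filament detection, removal classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scrollwave as sw
from scrollwave.analysis import (
    FilamentTrace,
    InsufficientActivationsError,
    default_v_iso,
)


def _pulse_train(period: float, n_periods: int = 10, dt_s: float = 0.02):
    """Synthetic periodic activation: short u=1 pulses on a 0 baseline."""
    t = np.arange(0.0, n_periods * period, dt_s)
    u = ((t % period) < 0.3).astype(float)
    return sw.ProbeSeries((0.0, 0.0, 0.0), t, u)


class TestActivationFrequency:
    def test_periodic_train_recovers_angular_frequency(self):
        series = _pulse_train(period=2.0)
        omega, cv = sw.activation_frequency(series, threshold=0.5)
        assert omega == pytest.approx(np.pi, rel=0.02)
        assert cv < 0.02

    def test_constant_series_raises(self):
        t = np.arange(0, 10, 0.05)
        series = sw.ProbeSeries((0, 0, 0), t, np.zeros_like(t))
        with pytest.raises(InsufficientActivationsError):
            sw.activation_frequency(series)

    def test_too_few_crossings_after_transient_discard(self):
        series = _pulse_train(period=2.0, n_periods=5)  # 5 crossings, 3 usable
        with pytest.raises(InsufficientActivationsError):
            sw.activation_frequency(series)

    @given(period=st.floats(0.5, 5.0))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_frequency_independent_of_pulse_shape_details(self, period):
        series = _pulse_train(period=period, n_periods=12, dt_s=period / 80)
        omega, _ = sw.activation_frequency(series)
        assert omega == pytest.approx(2 * np.pi / period, rel=0.03)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            sw.ProbeSeries((0, 0, 0), np.array([0.0, 1.0, 0.5]), np.zeros(3))


class TestDetectFilament:
    def test_quiescent_state_has_no_filament(self, params_tiny):
        dom = sw.free_domain(params_tiny)
        st_q = sw.quiescent_state(params_tiny)
        assert len(sw.detect_filament(st_q, dom, params_tiny)) == 0

    def test_crossed_linear_fields_give_vertical_line(self, params_tiny):
        # u = x - x0, v = y - y0 with isovalues 0: the intersection is the
        # vertical line (x0, y0, z)
        p = params_tiny
        dom = sw.free_domain(p)
        nx, ny, nz = p.grid_shape
        x = np.arange(nx) * p.dx
        y = np.arange(ny) * p.dx
        x0, y0 = 2.62, 3.11
        u = np.broadcast_to((x - x0)[:, None, None], p.grid_shape).copy()
        v = np.broadcast_to((y - y0)[None, :, None], p.grid_shape).copy()
        state = sw.MediumState(u, v)
        pts = sw.detect_filament(state, dom, p, u_iso=0.0, v_iso=0.0)
        assert len(pts) >= nz - 1
        assert np.abs(pts[:, 0] - x0).max() < p.dx / 2
        assert np.abs(pts[:, 1] - y0).max() < p.dx / 2

    def test_filament_points_exclude_obstacle(self, params_tiny):
        p = params_tiny
        dom = sw.default_domain(p, radius=1.0)
        rng = np.random.default_rng(3)
        state = sw.MediumState(
            rng.uniform(0, 1, p.grid_shape), rng.uniform(0, 0.8, p.grid_shape)
        )
        pts = sw.detect_filament(state, dom, p)
        if len(pts):
            d = np.linalg.norm(pts - np.asarray(dom.center), axis=1)
            assert d.min() > dom.radius - p.dx


def _trace_from_distances(radii, center=(0.0, 0.0, 0.0), R=1.0, dx=0.25):
    """Trace whose single filament point sits at the given distance from the
    obstacle surface at each integer time (None = no filament)."""
    tr = FilamentTrace(center, R, dx)
    for t, r in enumerate(radii):
        if r is None:
            tr.append(float(t), np.empty((0, 3)))
        else:
            tr.append(float(t), np.array([[R + r, 0.0, 0.0]]))
    return tr


class TestClassifyRemoval:
    def test_departure_times_definitional(self):
        # attached for 3 samples, detaches, leaves the box at t=5
        tr = _trace_from_distances([0.1, 0.1, 0.1, 0.5, 1.5, 9.0])
        out = sw.classify_removal(tr, box_half_width=5.0, t_limit=500.0)
        assert out.success
        assert out.t_detach == 3.0
        assert out.t_removed == 5.0

    def test_always_attached_is_failure(self):
        tr = _trace_from_distances([0.1] * 10)
        out = sw.classify_removal(tr, box_half_width=5.0, t_limit=500.0)
        assert not out.success
        assert out.t_detach is None
        assert out.t_removed is None

    def test_late_removal_fails_time_limit(self):
        tr = _trace_from_distances([0.1] * 10 + [9.0])
        out = sw.classify_removal(tr, box_half_width=5.0, t_limit=8.0)
        assert not out.success
        assert out.t_removed == 10.0

    def test_empty_filament_counts_as_removed(self):
        tr = _trace_from_distances([0.1, 0.1, None])
        out = sw.classify_removal(tr, box_half_width=5.0)
        assert out.success and out.t_removed == 2.0

    def test_empty_trace_rejected(self):
        tr = FilamentTrace((0, 0, 0), 1.0, 0.25)
        with pytest.raises(ValueError):
            sw.classify_removal(tr, box_half_width=5.0)

    @given(
        radii=st.lists(st.floats(0.0, 12.0), min_size=3, max_size=30),
        half1=st.floats(1.0, 6.0),
        grow=st.floats(0.1, 6.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_enlarging_box_cannot_shorten_removal_time(self, radii, half1, grow):
        tr = _trace_from_distances(radii)
        small = sw.classify_removal(tr, box_half_width=half1)
        big = sw.classify_removal(tr, box_half_width=half1 + grow)
        if big.t_removed is not None:
            assert small.t_removed is not None
            assert small.t_removed <= big.t_removed


class TestIsQuiescent:
    def test_zero_state(self, params_tiny):
        dom = sw.default_domain(params_tiny, radius=1.0)
        assert sw.is_quiescent(sw.quiescent_state(params_tiny), dom)

    def test_single_excited_voxel(self, params_tiny):
        dom = sw.default_domain(params_tiny, radius=1.0)
        st_one = sw.quiescent_state(params_tiny)
        st_one.u[2, 2, 2] = 1.0
        assert not sw.is_quiescent(st_one, dom)

    def test_obstacle_interior_ignored(self, params_tiny):
        dom = sw.default_domain(params_tiny, radius=1.0)
        st_in = sw.quiescent_state(params_tiny)
        ic = tuple(int(round(c / params_tiny.dx)) for c in dom.center)
        st_in.u[ic] = 1.0  # inside the obstacle: not tissue
        assert sw.is_quiescent(st_in, dom)


def test_default_recovery_isovalue_tracks_kinetics():
    assert default_v_iso(sw.ModelParams()) == pytest.approx(0.37)
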