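"""Field waveforms, surface forcing, and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scrollwave as sw
from scrollwave.fields import FieldKind


class TestFieldVector:
    def test_cpef_phase_convention_at_t0(self):
        assert sw.field_vector(sw.FieldSpec.cpef(1.8, 3.0), 0.0) == (1.8, 0.0, 0.0)

    def test_acef_half_period_reverses(self):
        spec = sw.FieldSpec.acef(2.0, 3.0)
        ex, ey, ez = sw.field_vector(spec, math.pi / 3.0)  # omega*t = pi
        assert ex == pytest.approx(-2.0, abs=1e-12)
        assert ey == ez == 0.0

    def test_pdcef_pulse_train_timing(self):
        spec = sw.FieldSpec.pdcef(2.0, 3.75, 0.1)  # period ~1.6755
        assert sw.field_vector(spec, 0.05) == (2.0, 0.0, 0.0)
        assert sw.field_vector(spec, 0.5) == (0.0, 0.0, 0.0)
        # second pulse
        period = 2.0 * math.pi / 3.75
        assert sw.field_vector(spec, period + 0.05) == (2.0, 0.0, 0.0)

    @given(t=st.floats(0.0, 100.0), we=st.floats(0.5, 10.0), e0=st.floats(0.0, 8.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_cpef_magnitude_constant(self, t, we, e0):
        ex, ey, ez = sw.field_vector(sw.FieldSpec.cpef(e0, we), t)
        assert math.hypot(ex, ey) == pytest.approx(e0, rel=1e-12, abs=1e-12)
        assert ez == 0.0

    def test_time_average_of_oscillatory_fields_vanishes(self):
        # integral over one full period is zero to quadrature accuracy
        for spec in (sw.FieldSpec.acef(2.0, 3.0), sw.FieldSpec.cpef(2.0, 3.0)):
            ts = np.linspace(0.0, spec.period, 20001)
            vecs = np.array([sw.field_vector(spec, t) for t in ts])
            mean = np.trapezoid(vecs, ts, axis=0) / spec.period
            np.testing.assert_allclose(mean, 0.0, atol=1e-6)

    def test_pdcef_duty_cycle_exact(self):
        spec = sw.FieldSpec.pdcef(2.0, 3.75, 0.1)
        ts = (np.arange(100000) + 0.5) / 100000 * spec.period
        on = np.array([sw.field_vector(spec, t)[0] != 0.0 for t in ts])
        assert on.mean() == pytest.approx(0.1 * 3.75 / (2 * math.pi), abs=1e-4)

    def test_none_kind_is_zero(self):
        assert sw.field_vector(sw.FieldSpec.none(), 1.23) == (0.0, 0.0, 0.0)


class TestSurfaceForcing:
    def test_cpef_pole_sees_nothing(self):
        spec = sw.FieldSpec.cpef(1.8, 3.0)
        for phi_az in (0.0, 1.0, 4.0):
            assert sw.surface_forcing(spec, 0.0, phi_az, 0.7) == pytest.approx(0.0, abs=1e-12)

    def test_acef_equator_max(self):
        assert sw.surface_forcing(sw.FieldSpec.acef(2.0, 3.0), math.pi / 2, 0.0, 0.0) \
            == pytest.approx(2.0, abs=1e-12)

    def test_pdcef_perpendicular_azimuth_zero(self):
        spec = sw.FieldSpec.pdcef(2.0, 3.75, 0.1)
        assert sw.surface_forcing(spec, math.pi / 2, math.pi / 2, 0.05) \
            == pytest.approx(0.0, abs=1e-12)

    def test_extremum_values(self):
        cpef = sw.FieldSpec.cpef(1.8, 3.0)
        assert sw.surface_forcing_extremum(cpef, math.pi / 2, 0.3) == pytest.approx(1.8)
        pdcef = sw.FieldSpec.pdcef(2.0, 3.75, 0.1)
        assert sw.surface_forcing_extremum(pdcef, math.pi / 4, 0.0) \
            == pytest.approx(2.0 * math.sin(math.pi / 4), rel=1e-12)

    @given(theta=st.floats(0.0, math.pi), phi_az=st.floats(0.0, 2 * math.pi))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_cpef_extremum_azimuth_free_and_dominates_acef(self, theta, phi_az):
        """The rotating field reaches every azimuth of the equator: its
        extremum is azimuth-independent and >= the x-directed field's."""
        cpef = sw.FieldSpec.cpef(2.0, 3.0)
        acef = sw.FieldSpec.acef(2.0, 3.0)
        e_cp = sw.surface_forcing_extremum(cpef, theta, phi_az)
        assert e_cp == pytest.approx(
            sw.surface_forcing_extremum(cpef, theta, 0.0), rel=1e-12, abs=1e-12
        )
        assert e_cp >= sw.surface_forcing_extremum(acef, theta, phi_az) - 1e-12

    @given(
        theta=st.floats(0.0, math.pi),
        phi_az=st.floats(0.0, 2 * math.pi),
        t=st.floats(0.0, 50.0),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_extremum_bounds_instantaneous_forcing(self, theta, phi_az, t):
        for spec in (
            sw.FieldSpec.cpef(1.8, 3.0),
            sw.FieldSpec.acef(2.0, 3.0),
            sw.FieldSpec.pdcef(2.0, 3.75, 0.1),
        ):
            inst = abs(sw.surface_forcing(spec, theta, phi_az, t))
            assert inst <= sw.surface_forcing_extremum(spec, theta, phi_az) + 1e-9


class TestSpecValidation:
    def test_pulse_duration_must_fit_in_period(self):
        with pytest.raises(ValueError):
            sw.FieldSpec.pdcef(2.0, 3.75, 2.0)  # period ~1.68 < d

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sw.FieldSpec.cpef(-1.0, 3.0)

    def test_kind_coercion_from_string(self):
        spec = sw.FieldSpec(kind="cpef", E0=1.0, omega_e=2.0)
        assert spec.kind is FieldKind.CPEF
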