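"""Phase-field obstacle geometry and the embedded boundary operator."""

import numpy as np
import pytest

import scrollwave as sw
from scrollwave.model import diffusion_and_forcing


@pytest.fixture()
def params():
    return sw.default_params(grid=40)


@pytest.fixture()
def domain(params):
    return sw.default_domain(params, radius=2.0)


class TestBuildPhaseField:
    def test_profile_values(self, params, domain):
        c = np.asarray(params.center)
        nx = params.grid_shape[0]
        x = np.arange(nx) * params.dx
        # center node: deep inside the obstacle
        ic = tuple(int(round(cc / params.dx)) for cc in c)
        assert domain.phi[ic] < 0.01
        # at |r - c| = R the tanh profile crosses 1/2; sample along +x
        r = np.abs(x - c[0])
        on_surface = np.argmin(np.abs(r - domain.radius))
        assert domain.phi[on_surface, ic[1], ic[2]] == pytest.approx(
            0.5, abs=0.25
        )  # nearest node within half a cell of the surface
        # far field saturates beyond R + 5 xi
        far = r - domain.radius > 5 * domain.interface_width
        assert far.any()
        assert domain.phi[far, ic[1], ic[2]].min() > 0.999

    def test_bounds_and_monotonicity(self, params, domain):
        assert domain.phi.min() >= 0.0 and domain.phi.max() <= 1.0
        # monotone non-decreasing in distance from the center
        c = np.asarray(params.center)
        nx, ny, nz = params.grid_shape
        x = np.arange(nx) * params.dx
        prof = domain.phi[:, int(round(c[1] / params.dx)), int(round(c[2] / params.dx))]
        right = prof[x >= c[0]]
        assert np.all(np.diff(right) >= -1e-12)

    def test_obstacle_touching_boundary_rejected(self, params):
        with pytest.raises(ValueError, match="margin"):
            sw.build_phase_field((1.0, 5.0, 5.0), 2.0, 0.5, params)

    def test_tiny_radius_rejected(self, params):
        with pytest.raises(ValueError, match="radius"):
            sw.build_phase_field(params.center, params.dx, 0.5, params)

    def test_unresolved_interface_rejected(self, params):
        with pytest.raises(ValueError, match="interface"):
            sw.build_phase_field(params.center, 2.0, 0.1 * params.dx, params)


class TestEmbeddedOperator:
    def test_uniform_field_has_zero_rate(self, params, domain):
        u = np.full(params.grid_shape, 0.3)
        rate = diffusion_and_forcing(u, domain, (0.0, 0.0, 0.0), params)
        active = domain.inv_phi > 0
        assert np.abs(rate[active]).max() < 1e-10

    def test_linear_field_harmonic_without_obstacle(self, params):
        dom = sw.free_domain(params)
        nx = params.grid_shape[0]
        x = np.arange(nx) * params.dx
        u = np.broadcast_to(x[:, None, None], params.grid_shape).copy()
        rate = diffusion_and_forcing(u, dom, (0.0, 0.0, 0.0), params)
        # interior: Laplacian of a linear profile vanishes; mirrored outer
        # boundary sees the kink, so exclude the two x-faces
        assert np.abs(rate[1:-1, :, :]).max() < 1e-10

    def test_no_flux_conservation_without_obstacle(self, params):
        # with phi == 1 and E = 0 the diffusion operator conserves the
        # discrete integral of u (single interior bump)
        dom = sw.free_domain(params)
        u = np.zeros(params.grid_shape)
        u[20, 20, 20] = 1.0
        rate = diffusion_and_forcing(u, dom, (0.0, 0.0, 0.0), params)
        assert abs(rate.sum()) * params.dt < 1e-10

    def test_depolarization_pattern_locks_forcing_sign(self, params, domain):
        """A static field along +x must depolarize the obstacle face the
        field points away from (-x face) and hyperpolarize the +x face."""
        state = sw.quiescent_state(params)
        # effectively-DC pulsed field over a short run
        spec = sw.FieldSpec.pdcef(1.0, 0.05, 10.0)
        sw.integrate(state, domain, spec, params, 0.5)
        ic = tuple(int(round(cc / params.dx)) for cc in params.center)
        off = int(round((domain.radius + 2 * params.dx) / params.dx))
        u_minus = state.u[ic[0] - off, ic[1], ic[2]]
        u_plus = state.u[ic[0] + off, ic[1], ic[2]]
        assert u_minus > 0.05
        assert u_plus < -0.02

    def test_obstacle_interior_held_at_rest(self, params, domain):
        state = sw.quiescent_state(params)
        spec = sw.FieldSpec.cpef(2.0, 3.0)
        sw.integrate(state, domain, spec, params, 1.0)
        interior = domain.phi < params.phi_floor
        assert np.abs(state.u[interior]).max() == 0.0
        assert np.abs(state.v[interior]).max() == 0.0
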