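"""Shared fixtures.

The heavyweight objects (60^3 reference medium, relaxed pinned scroll,
its rotation frequency) are built once per session and shared by every
scenario test; unit tests use much smaller grids.
"""

from __future__ import annotations

import numpy as np
import pytest

import scrollwave as sw
from scrollwave.experiments import measure_scroll_frequency


@pytest.fixture(scope="session")
def params_ref() -> sw.ModelParams:
    """Reference reduced-scale medium: 60^3, dx = 0.25."""
    return sw.default_params(grid=60)


@pytest.fixture(scope="session")
def domain_ref(params_ref) -> sw.PhaseFieldDomain:
    """Centered spherical obstacle, R = 3 (12 dx), xi = 2 dx."""
    return sw.default_domain(params_ref, radius=3.0)


@pytest.fixture(scope="session")
def pinned_ref(params_ref, domain_ref) -> sw.MediumState:
    """Scroll wave relaxed onto the obstacle, reused (copied) everywhere."""
    return sw.pinned_scroll_init(
        params_ref, domain_ref, sw.ScrollInitSpec(relaxation_time=20.0)
    )


@pytest.fixture(scope="session")
def omega_scroll_ref(params_ref, domain_ref, pinned_ref) -> float:
    """Rotation frequency of the pinned scroll, the reference for every
    omega_wave comparison."""
    omega, cv = measure_scroll_frequency(pinned_ref, domain_ref, params_ref)
    assert cv < 0.02, "pinned scroll frequency not stationary"
    return omega


@pytest.fixture()
def params_tiny() -> sw.ModelParams:
    """Small grid for cheap structural tests (no wave physics)."""
    return sw.default_params(grid=24)


@pytest.fixture(scope="session")
def removal_setup():
    """Elongated-box geometry used by the unpinning scenarios."""
    from scrollwave.experiments import removal_reference_setup

    return removal_reference_setup()


@pytest.fixture(scope="session")
def pinned_removal(removal_setup) -> sw.MediumState:
    params, domain = removal_setup
    return sw.pinned_scroll_init(params, domain, sw.ScrollInitSpec(relaxation_time=20.0))


@pytest.fixture(scope="session")
def reference_removal(removal_setup, pinned_removal):
    """One CPEF removal run at the saturating amplitude (E0=1.8,
    omega_e=3.5), shared by the removal-time and phase-diagram checks."""
    params, domain = removal_setup
    outcome, trace, final = sw.run_removal(
        sw.FieldSpec.cpef(1.8, 3.5), params, domain, pinned_removal,
        t_limit=500.0, stop_on="box", quiescence_wait=100.0,
    )
    return outcome, trace, final


@pytest.fixture(scope="session")
def cpef_scan_ref(params_ref, domain_ref, omega_scroll_ref):
    """Quiescent-medium CPEF frequency scan over the omega_e band used by
    the removal experiments."""
    from scrollwave.experiments import run_frequency_scan

    return run_frequency_scan(
        sw.FieldKind.CPEF, 1.8, [3.0, 3.25, 3.5, 3.75], params_ref,
        domain_ref, omega_scroll=omega_scroll_ref, t_end=50.0,
    )
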