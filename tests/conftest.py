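import numpy as np
import pytest

from irecar import ElectrodeConfig, build_domain, solve_field


@pytest.fixture(scope="session")
def thin_homogeneous_field():
    """Homogeneous slab with full-thickness needles: z-invariant, so the
    solution matches the 2-D two-wire problem.  Shared across tests."""
    electrodes = ElectrodeConfig(
        spacing_mm=5.0, electrode_radius_mm=0.5, applied_voltage_v=1250.0
    )
    domain = build_domain(
        tumor_diameter_mm=0.0,
        conductivities_s_per_m=(0.2, 0.2),
        electrodes=electrodes,
        resolution_mm=0.2,
        domain_thickness_mm=2.0,
    )
    return domain, solve_field(domain, electrodes)


@pytest.fixture(scope="session")
def small_tumor_solution():
    """Coarse 3-D tumor-in-tissue solve for coverage/symmetry tests."""
    electrodes = ElectrodeConfig(spacing_mm=5.0, applied_voltage_v=1250.0)
    domain = build_domain(
        tumor_diameter_mm=6.0,
        conductivities_s_per_m=(0.3, 0.1),
        electrodes=electrodes,
        resolution_mm=0.5,
    )
    return domain, electrodes, solve_field(domain, electrodes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
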