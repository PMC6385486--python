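import numpy as np
import pytest

import mdft_et as m
from mdft_et.fixtures import TOY_KERNEL_DEFAULTS, chlorine_state


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230815)


@pytest.fixture(scope="session")
def toy_solvent():
    return m.toy_dipolar_solvent()


@pytest.fixture(scope="session")
def quad8(toy_solvent):
    """2×2×2 product rule: exact for constants and first-order harmonics."""
    return m.build_orientation_quadrature(2, 2, 2, toy_solvent.symmetry_order)


@pytest.fixture(scope="session")
def small_grid():
    return m.build_spatial_grid((6.0, 6.0, 6.0), (6, 6, 6))


@pytest.fixture(scope="session")
def box16_grid():
    return m.build_spatial_grid((16.0, 16.0, 16.0), (16, 16, 16))


@pytest.fixture(scope="session")
def toy_kernel():
    return m.make_builtin_kernel("dipolar-toy", **TOY_KERNEL_DEFAULTS)


@pytest.fixture(scope="session")
def weak_kernel():
    """A milder anisotropic kernel for brute-force oracle comparisons."""
    return m.make_builtin_kernel(
        "dipolar-toy", a_s=-3.0, w_s=0.8, a_l=-2.0, w_l=1.1, a_t=1.5, w_t=0.9
    )


@pytest.fixture(scope="session")
def zero_kernel():
    return m.make_builtin_kernel("zero")


def make_redox_pair(q0, q1, position=(8.0, 8.0, 8.0)):
    s = chlorine_state(0.0, position=position)
    return s.with_charges([q0], f"q{q0:+g}"), s.with_charges([q1], f"q{q1:+g}")


@pytest.fixture(scope="session")
def charge_swap_scan_quadratic(box16_grid, quad8, toy_solvent, toy_kernel):
    """Quadratic-mode scan of a charge-inverting couple (+0.5 → −0.5)."""
    s0, s1 = make_redox_pair(0.5, -0.5)
    return m.run_eta_scan(
        s0, s1, toy_solvent, toy_kernel, box16_grid, quad8,
        m.EtaSchedule.uniform(11), ideal_mode="quadratic",
    )


@pytest.fixture(scope="session")
def anion_scan_exact(quad8, toy_solvent, toy_kernel):
    """Exact-mode scan of a neutral → anion-like couple on a coarse box."""
    grid = m.build_spatial_grid((12.0, 12.0, 12.0), (12, 12, 12))
    s0, s1 = make_redox_pair(0.0, -0.5, position=(6.0, 6.0, 6.0))
    return m.run_eta_scan(
        s0, s1, toy_solvent, toy_kernel, grid, quad8,
        m.EtaSchedule((0.0, 0.25, 0.5, 0.75, 1.0)), ideal_mode="exact",
    )
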