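import numpy as np
import pytest

from mitoreticulum.config import SimulationConfig
from mitoreticulum.cytoskeleton_mc import PolymerChain
from mitoreticulum.wlc_theory import CellDensities


@pytest.fixture(scope="session")
def ref_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def ref_densities(ref_config) -> CellDensities:
    """Reference-cell analytic densities (built once; also triggers the
    one-time spectral table build)."""
    return CellDensities(ref_config)


@pytest.fixture(scope="session")
def densities_psi_neg() -> CellDensities:
    return CellDensities(SimulationConfig(psi=-0.2))


@pytest.fixture(scope="session")
def densities_psi_pos() -> CellDensities:
    return CellDensities(SimulationConfig(psi=0.2))


def straight_chain(start, direction, L=1.0, a=0.02) -> PolymerChain:
    """Hand-placed straight polyline fixture (need not pass the origin)."""
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    n = int(L / a)
    verts = start + a * np.arange(n + 1)[:, None] * d
    return PolymerChain(vertices=verts, bond_length=a, bond_angle=0.0)
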