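import numpy as np
import pytest

from pemrelease import CompositeSphere, SolverGrid
from pemrelease.synthetic_data import default_geometry


@pytest.fixture
def nanoparticle() -> CompositeSphere:
    """The default 330 nm coated-nanoparticle geometry."""
    return default_geometry()


@pytest.fixture
def homogeneous_sphere() -> CompositeSphere:
    """Core and shell with identical transport: a homogeneous sphere r3 = 1."""
    return CompositeSphere(r1=0.45, r2=0.9, t=0.1, D1=1.0, D2=1.0, K=1.0)


@pytest.fixture
def fine_grid() -> SolverGrid:
    """Grid resolving the homogeneous-sphere release to a few 1e-4."""
    return SolverGrid(n_core=180, n_shell=32, dt=0.4 / 4000, t_end=0.4,
                      grading_ratio=100.0)
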