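"""Shared fixtures: baseline solves reused across the suite.

The pipeline is deterministic, so session-scoped solutions can be shared
freely between tests.
"""

import pytest

from lobuleflow.experiments import run_single_lobule, run_slab
from lobuleflow.geometry import SurfaceKind
from lobuleflow.parameters import PhysiologicalParameters

#: mesh edge length for quantitative checks [m]
H_FINE = 10e-6
#: mesh edge length for structural/property checks [m]
H_COARSE = 15e-6


@pytest.fixture(scope="session")
def params() -> PhysiologicalParameters:
    return PhysiologicalParameters()


@pytest.fixture(scope="session")
def lobule_run(params):
    """Baseline single-lobule solution at the quantitative mesh level."""
    return run_single_lobule(params, H_FINE)


@pytest.fixture(scope="session")
def square_run(params):
    return run_single_lobule(params, H_FINE, square=True)


@pytest.fixture(scope="session")
def gp_run(params):
    return run_slab(params, SurfaceKind.GLISSON_PERITONEAL, mesh_size=H_FINE)


@pytest.fixture(scope="session")
def ba_run(params):
    return run_slab(params, SurfaceKind.BARE_AREA, mesh_size=H_FINE)


@pytest.fixture(scope="session")
def coarse_lobule_run(params):
    return run_single_lobule(params, H_COARSE)
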