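"""Shared fixtures: small solved problems reused across test modules.

Everything is generated at run time; the expensive fixtures are
session-scoped so each is computed once.
"""

import numpy as np
import pytest

from sphincterfem import geometry as geo
from sphincterfem import meshing as msh
from sphincterfem import solver as sv


@pytest.fixture(scope="session")
def annulus_solution():
    """Spongy annulus (1 mm / 3 mm) at p = 1 Pa with symmetry constraints —
    the thick-walled-cylinder verification problem."""
    dom = geo.build_annulus_domain(1e-3, 3e-3)
    return sv.solve_case(
        "annulus",
        domain=dom,
        load=sv.LoadProgram(target_pressure=1.0, n_increments=1),
        settings=sv.SolverSettings(bc_mode="symmetry"),
        h_coarse=2e-4,
        h_fine=2e-4,
    )


@pytest.fixture(scope="session")
def annulus_mesh(annulus_solution):
    return annulus_solution.mesh


@pytest.fixture(scope="session")
def p0_low():
    """Sane sphincter at a low pressure (cleanly convergent, coarse mesh)."""
    return sv.solve_case(
        "P0",
        load=sv.LoadProgram(target_pressure=392.0, n_increments=4),
        h_coarse=6e-4,
        h_fine=3e-4,
    )


@pytest.fixture(scope="session")
def h6_mesh():
    """Default-resolution mesh of the six-hole configuration."""
    return msh.generate_mesh(geo.build_case("H6"), 5e-4, 2.5e-4)


@pytest.fixture(scope="session")
def small_annulus_mesh():
    """Tiny annulus mesh for assembly-level finite-difference oracles."""
    dom = geo.build_annulus_domain(1e-3, 1.8e-3)
    return msh.generate_mesh(dom, 4e-4, 4e-4)
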