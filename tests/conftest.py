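"""Shared fixtures: packaged configs, the default phantom, and the
session-scoped strategy runs that several suites inspect."""

import numpy as np
import pytest
from scipy import sparse

from autoplan.configio import load_objectives, load_rules, packaged_path
from autoplan.dose import BeamletBasis, InfluenceMatrix, KernelParams, beam_geometry, influence_matrix
from autoplan.phantom import Grid, Phantom, PhantomSpec, Structure, build_phantom
from autoplan.planner import dose_escalation_loop, oar_sparing_loop, planning_loop
from autoplan.scenarios import cohort_planner_options


@pytest.fixture(scope="session")
def phantom_objectives():
    return load_objectives(packaged_path("objectives_phantom"))


@pytest.fixture(scope="session")
def phantom_rules(phantom_objectives):
    return load_rules(packaged_path("rules_phantom"), phantom_objectives)


@pytest.fixture(scope="session")
def planner_opts():
    return cohort_planner_options()


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def asym_phantom():
    """The packaged asymmetric (unilateral nodal) phantom."""
    return build_phantom(PhantomSpec(laterality="unilateral"))


@pytest.fixture(scope="session")
def imrt_matrix(default_phantom):
    basis = beam_geometry("imrt7", default_phantom)
    return influence_matrix(basis, default_phantom, KernelParams())


@pytest.fixture(scope="session")
def std_imrt(default_phantom, imrt_matrix, phantom_objectives, phantom_rules, planner_opts):
    return planning_loop(default_phantom, imrt_matrix, phantom_objectives,
                         phantom_rules, planner_opts)


@pytest.fixture(scope="session")
def spare_imrt(default_phantom, imrt_matrix, phantom_objectives, phantom_rules, planner_opts):
    return oar_sparing_loop(default_phantom, imrt_matrix, phantom_objectives,
                            phantom_rules, "parotids", planner_opts)


@pytest.fixture(scope="session")
def esc_imrt(default_phantom, imrt_matrix, phantom_objectives, phantom_rules, planner_opts):
    return dose_escalation_loop(default_phantom, imrt_matrix, phantom_objectives,
                                phantom_rules, planner_opts)


@pytest.fixture(scope="session")
def esc_arc(default_phantom, phantom_objectives, phantom_rules, planner_opts):
    basis = beam_geometry("arc", default_phantom, spacing_deg=10.0)
    matrix = influence_matrix(basis, default_phantom, KernelParams())
    return dose_escalation_loop(default_phantom, matrix, phantom_objectives,
                                phantom_rules, planner_opts)


# ---------------------------------------------------------------------------
# tiny hand-built objects for unit tests


def make_toy_phantom(masks: dict[str, np.ndarray], shape, roles: dict[str, str] | None = None,
                     prescriptions=(70.0, 63.0, 56.0)) -> Phantom:
    """A phantom assembled directly from boolean masks (no geometry engine)."""
    grid = Grid(tuple(shape), tuple(1.0 for _ in shape), tuple(0.0 for _ in shape))
    roles = roles or {}
    structures = {
        "body": Structure("body", "body", np.ones(shape, dtype=bool)),
    }
    for name, m in masks.items():
        role = roles.get(name, "target")
        structures[name] = Structure(name, role, np.asarray(m, dtype=bool).reshape(shape))
    return Phantom(grid=grid, structures=structures, prescriptions_gy=prescriptions)


def make_toy_matrix(entries: np.ndarray, grid_shape) -> InfluenceMatrix:
    """An influence matrix wrapped around an explicit dense entries array."""
    entries = np.asarray(entries, dtype=float)
    basis = BeamletBasis("imrt7", (0.0,), [np.arange(entries.shape[1], dtype=float)])
    grid = Grid(tuple(grid_shape), tuple(1.0 for _ in grid_shape),
                tuple(0.0 for _ in grid_shape))
    return InfluenceMatrix(sparse.csr_matrix(entries), basis, grid, KernelParams(),
                           np.arange(entries.shape[1]))
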