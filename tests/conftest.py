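"""Shared fixtures: reference materials, meshes and RVE problems.

Session-scoped where construction is expensive (the RVE problems factorize
their operators once and cache effective tangents).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from bonefe2 import (
    RVEParams,
    RVEProblem,
    TimeIntegrationConfig,
    build_rve_mesh,
)
from bonefe2.materials import bone_marrow, build_tensors, cortical_bone

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

MICRO_DT = 1e-3


@pytest.fixture(scope="session")
def micro_cfg() -> TimeIntegrationConfig:
    return TimeIntegrationConfig(dt=MICRO_DT)


@pytest.fixture(scope="session")
def bone_tensors():
    return build_tensors(cortical_bone())


@pytest.fixture(scope="session")
def marrow_tensors():
    return build_tensors(bone_marrow(MICRO_DT))


@pytest.fixture(scope="session")
def healthy_mesh():
    """Coarse 6^3 mesh of the healthy-bone RVE (a=0.32, b=0.36)."""
    return build_rve_mesh(RVEParams(0.32, 0.36, 2))


@pytest.fixture(scope="session")
def healthy_rve(healthy_mesh, bone_tensors, marrow_tensors, micro_cfg):
    return RVEProblem(healthy_mesh, bone_tensors, marrow_tensors, micro_cfg)


@pytest.fixture(scope="session")
def degenerated_rve(bone_tensors, marrow_tensors, micro_cfg):
    mesh = build_rve_mesh(RVEParams(0.43, 0.14, 2))
    return RVEProblem(mesh, bone_tensors, marrow_tensors, micro_cfg)


@pytest.fixture(scope="session")
def homogeneous_rve(bone_tensors, micro_cfg):
    """Both phases carry the bone tensors: the uniform-field limit."""
    mesh = build_rve_mesh(RVEParams(0.32, 0.36, 1))
    return RVEProblem(mesh, bone_tensors, bone_tensors, micro_cfg)


def table1_cube_load() -> np.ndarray:
    """Microscale cube benchmark strain: eps_yz = 1e-5 (Voigt slot 4)."""
    eps = np.zeros(6)
    eps[4] = 1e-5
    return eps
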