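"""Shared fixtures.

The heavy session fixtures build one default synthetic cohort (17+17, 4 mm
grid) and its derived quantities once, shared by the acceptance-style tests.
Unit tests use a coarse 8 mm grid (same brain geometry, ~2,300 voxels) or
tiny hand-built grids.
"""

import numpy as np
import pytest

import neurosem as ns
from neurosem.io_core import AUTISM, CONTROL, VoxelGrid
from neurosem.pipeline import derive_cohort, group_solution

#: Frozen seed of the default study cohort used across the test suite.
COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    datasets, metas, truth = ns.simulate_cohort(seed=COHORT_SEED)
    return datasets, metas, truth


@pytest.fixture(scope="session")
def default_derived(default_cohort):
    datasets, metas, _ = default_cohort
    return derive_cohort(datasets, metas)


@pytest.fixture(scope="session")
def group_solutions(default_cohort, default_derived):
    _, metas, _ = default_cohort
    out = {}
    for g in (AUTISM, CONTROL):
        members = [p for p, m in zip(default_derived, metas) if m.group == g]
        out[g] = (members, group_solution(members, group=g))
    return out


@pytest.fixture(scope="session")
def coarse_grid():
    """Same brain geometry at 8 mm: fast, all planted regions in-mask."""
    return ns.default_grid(spacing_mm=8.0)


@pytest.fixture(scope="session")
def coarse_cohort(coarse_grid):
    """Small, coarse cohort for protocol-level unit tests."""
    cfg = ns.CohortConfig(n_per_group=4)
    return ns.simulate_cohort(cfg, seed=7, grid=coarse_grid)


@pytest.fixture
def tiny_grid():
    """4x4x4 grid at 4 mm, full mask, origin at voxel (0,0,0)."""
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    return VoxelGrid(affine=affine, mask=np.ones((4, 4, 4), dtype=bool))


def noise_free_config(**kwargs):
    """Generator settings that make the signal exactly deterministic."""
    base = dict(noise_sigma=0.0, score_jitter=0.0, center_jitter_mm=0.0,
                n_idiosyncratic=0, amp_sd=0.0, self_autism_sd=0.0)
    base.update(kwargs)
    return ns.CohortConfig(**base)
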