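"""Cohort-level plumbing shared by the decoding protocols and analyses.

Per-participant quantities (stability map, stable-voxel selection, first-level
factor solution, block-mean profile) depend only on that participant's own
data, so they are computed once and reused across leave-one-out folds; only
the group-level factor analysis is refit per fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import ActivationDataset, ItemSet, ParticipantMeta, VoxelGrid
from .factor_pipeline import (FactorSolutionL1, GroupFactorSolution, SphereSet,
                              factor_sphere_sets, fit_first_level,
                              fit_group_level)
from .synthetic_cohort import REGION_CENTERS
from .voxel_selection import (VoxelSelection, region_masks_from_centers,
                              select_stable_voxels, voxel_stability)

__all__ = [
    "ParticipantDerived",
    "default_regions",
    "derive_participant",
    "derive_cohort",
    "group_solution",
    "word_length_factor_index",
    "semantic_sphere_set",
    "full_sphere_set",
]


def default_regions(grid: VoxelGrid, radius_mm: float = 16.0):
    """The five default selection areas: the factor-region neighborhoods."""
    return region_masks_from_centers(grid, REGION_CENTERS, radius_mm=radius_mm)


@dataclass
class ParticipantDerived:
    """Cached single-participant derivations (fold-independent)."""

    dataset: ActivationDataset
    meta: ParticipantMeta | None
    stability: np.ndarray          # all-6-block stability, (V,)
    selection: VoxelSelection
    l1: FactorSolutionL1
    profile: np.ndarray            # (16, V) block-mean activation

    @property
    def id(self) -> str:
        return self.dataset.participant_id


def derive_participant(d: ActivationDataset,
                       regions,
                       meta: ParticipantMeta | None = None,
                       n_factors: int = 7,
                       total_voxels: int = 135) -> ParticipantDerived:
    stab = voxel_stability(d)
    sel = select_stable_voxels(stab, regions, d.grid, total=total_voxels,
                               participant_id=d.participant_id)
    l1 = fit_first_level(d, sel, n_factors=n_factors)
    return ParticipantDerived(dataset=d, meta=meta, stability=stab,
                              selection=sel, l1=l1, profile=d.block_mean())


def derive_cohort(datasets: list[ActivationDataset],
                  metas: list[ParticipantMeta] | None = None,
                  regions=None,
                  n_factors: int = 7,
                  total_voxels: int = 135) -> list[ParticipantDerived]:
    grid = datasets[0].grid
    regions = regions if regions is not None else default_regions(grid)
    metas = metas or [None] * len(datasets)
    return [derive_participant(d, regions, meta=m, n_factors=n_factors,
                               total_voxels=total_voxels)
            for d, m in zip(datasets, metas)]


def group_solution(members: list[ParticipantDerived],
                   group: str = "",
                   n_factors: int = 4) -> GroupFactorSolution:
    grid = members[0].dataset.grid
    return fit_group_level([m.l1 for m in members], grid, group=group,
                           n_factors=n_factors)


def word_length_factor_index(sol: GroupFactorSolution, items: ItemSet) -> int:
    """The group factor most correlated (|r|) with verb letter counts."""
    letters = items.letter_count_vector()
    r = [abs(np.corrcoef(sol.scores[:, j], letters)[0, 1])
         for j in range(sol.n_factors)]
    return int(np.argmax(r))


def semantic_sphere_set(sol: GroupFactorSolution, items: ItemSet,
                        max_spheres: int = 6) -> SphereSet:
    """Spheres of the 3 semantic factors (word-length factor excluded)."""
    wl = word_length_factor_index(sol, items)
    sets = factor_sphere_sets(sol, max_spheres=max_spheres)
    spheres = []
    for g, ss in enumerate(sets):
        if g == wl:
            continue
        spheres.extend(ss.spheres)
    return SphereSet(spheres=spheres)


def full_sphere_set(sol: GroupFactorSolution,
                    max_spheres: int = 6) -> SphereSet:
    """Spheres of all 4 group factors (the 24-sphere item-decoding set)."""
    sets = factor_sphere_sets(sol, max_spheres=max_spheres)
    return SphereSet(spheres=[s for ss in sets for s in ss.spheres])
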