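"""Voxel stability and region-quota selection of the most stable voxels.

The stability of a voxel is the mean Pearson correlation, over all pairs of
presentation blocks, of its 16-item activation profile.  Highly stable voxels
respond reproducibly to the stimulus set and carry the factor structure; the
analysis keeps the 135 most stable voxels per participant, spread over 5
configurable brain areas with an equal per-area quota.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_core import ActivationDataset, VoxelGrid

__all__ = [
    "StabilityMap",
    "VoxelSelection",
    "voxel_stability",
    "stability_from_blocks",
    "select_stable_voxels",
    "region_masks_from_centers",
]


def stability_from_blocks(block_profiles: np.ndarray) -> np.ndarray:
    """Mean pairwise-block correlation of per-voxel item profiles.

    Parameters
    ----------
    block_profiles : (n_blocks, n_items, V) array
        Per-block item-response profiles for each voxel.

    Returns
    -------
    (V,) array of stabilities in [-1, 1].  A block profile with zero variance
    contributes correlation 0 to every pair it participates in, so a dead or
    clipped voxel cannot poison the selection.
    """
    b, n, _ = block_profiles.shape
    if b < 2:
        raise ValueError("stability requires at least 2 blocks")
    z = block_profiles - block_profiles.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, z / sd, 0.0)
    # Sum over block pairs of z_b . z_b' = (||sum_b z||^2 - sum_b ||z||^2) / 2.
    tot = (z.sum(axis=0) ** 2).sum(axis=0)
    per = (z ** 2).sum(axis=1).sum(axis=0)
    pair_sum = (tot - per) / 2.0
    n_pairs = b * (b - 1) / 2.0
    return pair_sum / ((n - 1) * n_pairs)


def voxel_stability(d: ActivationDataset,
                    blocks: Sequence[int] | None = None) -> np.ndarray:
    """Per-voxel stability of ``d`` over the given (0-based) block subset.

    Defaults to all 6 blocks; at least 2 are required.
    """
    if blocks is None:
        blocks = range(d.data.shape[1])
    blocks = list(blocks)
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks to compute stability")
    profiles = d.data[:, blocks, :].transpose(1, 0, 2)  # (b, items, V)
    return stability_from_blocks(profiles)


#: StabilityMap is simply a (V,) float array aligned with grid.mask_indices.
StabilityMap = np.ndarray


@dataclass
class VoxelSelection:
    """The selected voxels of one participant, ordered region-by-region with
    descending stability inside each region."""

    participant_id: str
    indices: np.ndarray        # (n_selected,) indices into the in-mask axis
    stabilities: np.ndarray    # (n_selected,)
    regions: list[str]         # region name per selected voxel
    coords_mm: np.ndarray      # (n_selected, 3)

    def __len__(self) -> int:
        return len(self.indices)


def select_stable_voxels(stability: np.ndarray,
                         regions: Sequence[tuple[str, np.ndarray]],
                         grid: VoxelGrid,
                         total: int = 135,
                         quotas: Sequence[int] | None = None,
                         participant_id: str = "") -> VoxelSelection:
    """Select the ``total`` most stable voxels under a per-region quota rule.

    ``regions`` is a sequence of (name, boolean mask over the in-mask voxel
    axis); masks must be pairwise disjoint.  By default the quota is equal
    across regions (135 voxels over 5 areas -> 27 each).  Ties are broken by
    voxel index.
    """
    stability = np.asarray(stability, dtype=float)
    n_regions = len(regions)
    if quotas is None:
        if total % n_regions:
            raise ValueError(f"total {total} not divisible by {n_regions} regions")
        quotas = [total // n_regions] * n_regions
    if sum(quotas) != total:
        raise ValueError("quotas must sum to total")

    seen = np.zeros(stability.shape[0], dtype=bool)
    idx_all, stab_all, name_all = [], [], []
    for (name, mask), quota in zip(regions, quotas):
        mask = np.asarray(mask, dtype=bool)
        if (mask & seen).any():
            raise ValueError("region masks must be disjoint")
        seen |= mask
        cand = np.flatnonzero(mask)
        if len(cand) < quota:
            raise ValueError(
                f"region {name!r} has {len(cand)} voxels, fewer than its quota {quota}")
        # descending stability, ties by ascending voxel index
        order = np.lexsort((cand, -stability[cand]))[:quota]
        idx_all.append(cand[order])
        stab_all.append(stability[cand[order]])
        name_all.extend([name] * quota)

    indices = np.concatenate(idx_all)
    if len(np.unique(indices)) != len(indices):
        raise ValueError("internal error: duplicate voxels selected")
    return VoxelSelection(participant_id=participant_id,
                          indices=indices,
                          stabilities=np.concatenate(stab_all),
                          regions=name_all,
                          coords_mm=grid.coords_mm[indices])


def region_masks_from_centers(grid: VoxelGrid,
                              centers: dict[str, Sequence[Sequence[float]]],
                              radius_mm: float = 16.0,
                              ) -> list[tuple[str, np.ndarray]]:
    """Disjoint region masks: every in-mask voxel within ``radius_mm`` of any
    listed center is assigned to the region owning its nearest center (ties go
    to the earlier region in iteration order)."""
    coords = grid.coords_mm
    n = coords.shape[0]
    best = np.full(n, np.inf)
    owner = np.full(n, -1)
    for k, (_, ctrs) in enumerate(centers.items()):
        for c in ctrs:
            dist = np.linalg.norm(coords - np.asarray(c, dtype=float), axis=1)
            take = (dist <= radius_mm) & (dist < best)
            best[take] = dist[take]
            owner[take] = k
    out = []
    for k, name in enumerate(centers):
        out.append((name, owner == k))
    if not any(m.any() for _, m in out):
        warnings.warn("no in-mask voxel falls inside any region")
    return out
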