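"""Containers and file I/O for item-resolved fMRI activation datasets.

The analyses operate on per-participant activation tensors indexed
(item, presentation block, voxel), where the 16 items are 8 social-interaction
verbs each considered from the agent and the recipient perspective, and the
voxels live on a common grid shared by every participant of a cohort.

On disk a dataset is a 4D NIfTI-1 volume (one 3D volume per item x block,
out-of-brain voxels stored as NaN) plus a TSV sidecar labelling each volume
with its verb, role and block.  A cohort adds a participants TSV with group
membership, demographics, tract-density scalars and behavioral scores.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VERBS",
    "ROLES",
    "AUTISM",
    "CONTROL",
    "N_ITEMS",
    "N_BLOCKS",
    "FormatError",
    "GridMismatchError",
    "ItemSet",
    "VoxelGrid",
    "ActivationDataset",
    "ParticipantMeta",
    "load_dataset",
    "write_dataset",
    "load_cohort",
    "write_cohort",
]

#: Canonical verb order; agent precedes recipient within each verb.
VERBS = ("compliment", "insult", "adore", "hate", "hug", "kick",
         "encourage", "humiliate")
ROLES = ("agent", "recipient")

AUTISM = "autism"
CONTROL = "control"
GROUPS = (AUTISM, CONTROL)

N_ITEMS = 16
N_BLOCKS = 6


class FormatError(ValueError):
    """An on-disk dataset violates the expected layout or labelling."""


class GridMismatchError(ValueError):
    """Two datasets of one cohort do not share the common voxel grid."""


@dataclass(frozen=True)
class ItemSet:
    """The 16 social-interaction stimuli: 8 verbs x {agent, recipient}."""

    items: tuple[tuple[str, str], ...]

    def __post_init__(self):
        verbs = {v for v, _ in self.items}
        roles = {r for _, r in self.items}
        if len(self.items) != N_ITEMS or len(set(self.items)) != N_ITEMS:
            raise ValueError("an ItemSet must hold 16 distinct (verb, role) pairs")
        if len(verbs) != 8 or roles != set(ROLES):
            raise ValueError("expected 8 distinct verbs x 2 roles")

    @property
    def labels(self) -> list[str]:
        return [f"{v}/{r}" for v, r in self.items]

    @property
    def letter_counts(self) -> dict[str, int]:
        """Characters in each verb name (drives the word-length factor)."""
        return {v: len(v) for v, _ in self.items}

    def letter_count_vector(self) -> np.ndarray:
        """Per-item verb length, in canonical item order."""
        return np.array([len(v) for v, _ in self.items], dtype=float)

    def index(self, verb: str, role: str) -> int:
        return self.items.index((verb, role))


def canonical_item_set() -> ItemSet:
    items = tuple((v, r) for v in VERBS for r in ROLES)
    return ItemSet(items=items)


@dataclass
class VoxelGrid:
    """Common voxel grid: affine voxel-index -> mm map plus an in-brain mask."""

    affine: np.ndarray          # (4, 4), invertible
    mask: np.ndarray            # (X, Y, Z) bool

    _mask_indices: np.ndarray | None = field(default=None, repr=False, compare=False)
    _coords_mm: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.mask.ndim != 3 or not self.mask.any():
            raise ValueError("mask must be a nonempty 3D boolean array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def mask_indices(self) -> np.ndarray:
        """(V, 3) integer voxel indices of the in-mask voxels, C order."""
        if self._mask_indices is None:
            self._mask_indices = np.argwhere(self.mask)
        return self._mask_indices

    @property
    def coords_mm(self) -> np.ndarray:
        """(V, 3) mm coordinates of the in-mask voxels."""
        if self._coords_mm is None:
            ijk = self.mask_indices
            self._coords_mm = nib.affines.apply_affine(self.affine, ijk)
        return self._coords_mm

    def same_as(self, other: "VoxelGrid") -> bool:
        return (self.mask.shape == other.mask.shape
                and np.allclose(self.affine, other.affine)
                and np.array_equal(self.mask, other.mask))


@dataclass
class ActivationDataset:
    """One participant's (item, block, voxel) activation tensor.

    ``data`` holds only in-mask voxels, shape (16, 6, V), in the canonical
    item order of ``items`` and with 0-based block axis.  Values are
    percent-signal-change-like and unitless.
    """

    participant_id: str
    data: np.ndarray
    grid: VoxelGrid
    items: ItemSet

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        expected = (N_ITEMS, N_BLOCKS, self.grid.n_voxels)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != {expected}")
        if not np.isfinite(self.data).all():
            raise ValueError("activation values must all be finite")

    def block_mean(self) -> np.ndarray:
        """(16, V) item-by-voxel matrix averaged over the 6 blocks."""
        return self.data.mean(axis=1)


# Missing values (e.g. an absent Benton score) are carried as NaN and written
# as empty TSV cells; they are never silently imputed.
_META_FLOAT_FIELDS = ("age", "fsiq", "tract_density_L", "tract_density_R",
                      "benton", "wms_faces", "eyes", "ados_social")


@dataclass
class ParticipantMeta:
    """Demographics, anatomy and behavior for one participant."""

    id: str
    group: str
    age: float
    fsiq: float = np.nan
    tract_density_L: float = np.nan
    tract_density_R: float = np.nan
    benton: float = np.nan
    wms_faces: float = np.nan
    eyes: float = np.nan
    ados_social: float = np.nan

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")


def _sidecar_frame(items: ItemSet) -> pd.DataFrame:
    """Canonical sidecar: volume = item * 6 + block, blocks numbered 1..6."""
    rows = []
    for i, (verb, role) in enumerate(items.items):
        for b in range(N_BLOCKS):
            rows.append((i * N_BLOCKS + b, verb, role, b + 1))
    return pd.DataFrame(rows, columns=["volume_index", "verb", "role", "block"])


def write_dataset(d: ActivationDataset, out_prefix: str | os.PathLike) -> tuple[str, str]:
    """Write ``{prefix}.nii`` (4D, canonical volume order, NaN outside the
    brain mask) and ``{prefix}.tsv`` (volume labels).  Returns the two paths."""
    out_prefix = os.fspath(out_prefix)
    nii_path, tsv_path = out_prefix + ".nii", out_prefix + ".tsv"

    vol = np.full(d.grid.shape + (N_ITEMS * N_BLOCKS,), np.nan)
    flat = d.data.reshape(N_ITEMS * N_BLOCKS, -1)  # (96, V)
    mx, my, mz = d.grid.mask_indices.T
    vol[mx, my, mz, :] = flat.T
    img = nib.Nifti1Image(vol, d.grid.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, nii_path)

    _sidecar_frame(d.items).to_csv(tsv_path, sep="\t", index=False)
    return nii_path, tsv_path


def load_dataset(volume_path: str | os.PathLike,
                 sidecar_path: str | os.PathLike,
                 participant_id: str | None = None) -> ActivationDataset:
    """Assemble a dataset from a 4D NIfTI plus its TSV sidecar.

    The tensor is returned in canonical (item, block) order regardless of the
    on-disk volume order recorded in the sidecar.  The in-brain mask is the
    set of voxels with finite values in every volume.
    """
    img = nib.load(os.fspath(volume_path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise FormatError(f"expected a 4D volume, got shape {vol.shape}")
    side = pd.read_csv(sidecar_path, sep="\t")
    required = {"volume_index", "verb", "role", "block"}
    if not required.issubset(side.columns) or side[list(required)].isna().any().any():
        raise FormatError("sidecar must provide complete volume_index/verb/role/block columns")
    if len(side) != vol.shape[3]:
        raise FormatError(
            f"sidecar has {len(side)} rows but the volume holds {vol.shape[3]} images")

    items = canonical_item_set()
    mask = np.isfinite(vol).all(axis=3)
    if not mask.any():
        raise FormatError("no voxel is finite across all volumes")
    grid = VoxelGrid(affine=np.asarray(img.affine), mask=mask)
    mx, my, mz = grid.mask_indices.T
    flat = vol[mx, my, mz, :].T  # (n_volumes, V)

    data = np.empty((N_ITEMS, N_BLOCKS, grid.n_voxels))
    seen = set()
    for _, row in side.iterrows():
        verb, role = str(row["verb"]), str(row["role"])
        try:
            item = items.index(verb, role)
        except ValueError:
            raise FormatError(f"unknown item label {verb!r}/{role!r}") from None
        block = int(row["block"]) - 1
        if not 0 <= block < N_BLOCKS:
            raise FormatError(f"block {row['block']} outside 1..{N_BLOCKS}")
        if (item, block) in seen:
            raise FormatError(f"duplicate (item, block) label {verb}/{role} block {block + 1}")
        seen.add((item, block))
        vidx = int(row["volume_index"])
        if not 0 <= vidx < flat.shape[0]:
            raise FormatError(f"volume_index {vidx} out of range")
        data[item, block] = flat[vidx]

    if participant_id is None:
        base = os.path.basename(os.fspath(volume_path))
        participant_id = base[:-4] if base.endswith(".nii") else base
    return ActivationDataset(participant_id=participant_id, data=data,
                             grid=grid, items=items)


def metas_to_frame(metas: Sequence[ParticipantMeta]) -> pd.DataFrame:
    cols = ["id", "group"] + list(_META_FLOAT_FIELDS)
    return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in metas])


def frame_to_metas(df: pd.DataFrame) -> list[ParticipantMeta]:
    metas = []
    for _, row in df.iterrows():
        kwargs = {"id": str(row["id"]), "group": str(row["group"])}
        for c in _META_FLOAT_FIELDS:
            v = row.get(c, np.nan)
            kwargs[c] = float(v) if pd.notna(v) else np.nan
        metas.append(ParticipantMeta(**kwargs))
    return metas


def write_cohort(datasets: Sequence[ActivationDataset],
                 metas: Sequence[ParticipantMeta],
                 out_dir: str | os.PathLike) -> str:
    """Write every dataset plus ``participants.tsv``; returns the TSV path."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    by_id = {d.participant_id for d in datasets}
    if by_id != {m.id for m in metas}:
        raise ValueError("datasets and metas must cover the same participant ids")
    for d in datasets:
        write_dataset(d, os.path.join(out_dir, d.participant_id))
    tsv = os.path.join(out_dir, "participants.tsv")
    metas_to_frame(metas).to_csv(tsv, sep="\t", index=False, na_rep="")
    return tsv


def load_cohort(participants_tsv: str | os.PathLike,
                data_dir: str | os.PathLike | None = None,
                ) -> tuple[list[ActivationDataset], list[ParticipantMeta]]:
    """Load all participants listed in a cohort TSV and verify the shared grid."""
    participants_tsv = os.fspath(participants_tsv)
    if data_dir is None:
        data_dir = os.path.dirname(participants_tsv)
    metas = frame_to_metas(pd.read_csv(participants_tsv, sep="\t"))
    datasets = []
    for m in metas:
        prefix = os.path.join(os.fspath(data_dir), m.id)
        d = load_dataset(prefix + ".nii", prefix + ".tsv", participant_id=m.id)
        if datasets and not d.grid.same_as(datasets[0].grid):
            raise GridMismatchError(
                f"participant {m.id!r} is not on the cohort's common grid")
        datasets.append(d)
    return datasets, metas
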