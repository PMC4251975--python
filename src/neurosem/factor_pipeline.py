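"""Two-level exploratory factor analysis of stable-voxel activation.

Level 1 factors each participant's 16-item x 135-voxel block-averaged
activation (principal-component extraction on the voxel correlation matrix,
varimax rotation, regression-method item scores; 7 factors).  Level 2 factors
the pooled first-level score vectors of all participants of a group into 4
group factors, traces each group factor back to the originating voxels, and
summarizes their spatial clusters as spheres (the factor-associated brain
locations).  Recovered factors are identified by maximum-|correlation|
matching of their 16-item score vectors against reference score templates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_core import ActivationDataset, VoxelGrid, N_ITEMS
from .voxel_selection import VoxelSelection

__all__ = [
    "kaiser_count",
    "varimax",
    "varimax_criterion",
    "FactorSolutionL1",
    "GroupFactorSolution",
    "Sphere",
    "SphereSet",
    "fit_first_level",
    "fit_group_level",
    "cluster_to_spheres",
    "match_factors",
    "FactorMatch",
]


def kaiser_count(eigenvalues: np.ndarray) -> int:
    """Number of eigenvalues strictly greater than 1 (Kaiser criterion)."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue vector")
    return int((ev > 1.0).sum())


def varimax_criterion(loadings: np.ndarray, normalize: bool = True) -> float:
    """Varimax objective: sum over factors of the variance of squared
    (optionally Kaiser row-normalized) loadings."""
    L = np.asarray(loadings, dtype=float)
    if normalize:
        h = np.sqrt((L ** 2).sum(axis=1, keepdims=True))
        h[h == 0] = 1.0
        L = L / h
    sq = L ** 2
    return float((sq.var(axis=0)).sum())


def varimax(loadings: np.ndarray,
            tol: float = 1e-10,
            max_iter: int = 2000,
            normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation (SVD algorithm, Kaiser normalization).

    Returns (rotated loadings, rotation matrix) with ``rotated = L @ R`` and
    ``R`` orthonormal.  Columns are sign-fixed so the largest-|loading| entry
    of each factor is positive.  If the criterion has not converged within
    ``max_iter`` sweeps a warning is issued and the best iterate returned.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        raise ValueError("varimax needs at least 2 factors")
    h = np.ones((p, 1))
    if normalize:
        h = np.sqrt((L ** 2).sum(axis=1, keepdims=True))
        h[h == 0] = 1.0
        L = L / h

    # Kaiser's pairwise planar rotations: each (j, l) pair is rotated by the
    # closed-form optimal angle, so symmetric saddle points (e.g. a perfect
    # 45-degree mixture) are escaped rather than stalled at.
    Lam = L.copy()
    R = np.eye(k)
    converged = False
    crit_old = varimax_criterion(Lam, normalize=False)
    for _ in range(max_iter):
        for j in range(k - 1):
            for l in range(j + 1, k):
                x, y = Lam[:, j], Lam[:, l]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (u @ v - u.sum() * v.sum() / p)
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                Lam[:, [j, l]] = Lam[:, [j, l]] @ rot
                R[:, [j, l]] = R[:, [j, l]] @ rot
        crit = varimax_criterion(Lam, normalize=False)
        if crit - crit_old <= tol * max(crit_old, 1e-12):
            converged = True
            break
        crit_old = crit
    if not converged:
        warnings.warn("varimax did not converge; returning best iterate")

    rotated = Lam * h
    # sign convention: dominant entry of each column positive
    for j in range(k):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
            R[:, j] = -R[:, j]
    return rotated, R


@dataclass
class FactorSolutionL1:
    """First-level (per-participant) factor solution."""

    participant_id: str
    loadings: np.ndarray        # (n_vars, n_factors) rotated voxel loadings
    scores: np.ndarray          # (16, n_factors), column-standardized
    assignment: np.ndarray      # (n_vars,) factor index per voxel, -1 = none
    eigenvalues: np.ndarray     # spectrum of the voxel correlation matrix
    selection: VoxelSelection   # the voxels the columns refer to
    kept: np.ndarray            # indices into selection of non-constant voxels


@dataclass
class Sphere:
    """A factor-associated brain location."""

    center_mm: np.ndarray
    radius_mm: float
    factor: str = ""
    source_group: str = ""
    n_members: int = 0

    def contains(self, coords_mm: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(np.asarray(coords_mm) - self.center_mm, axis=-1)
        return d <= self.radius_mm


@dataclass
class SphereSet:
    spheres: list[Sphere]

    def __len__(self) -> int:
        return len(self.spheres)

    def __iter__(self):
        return iter(self.spheres)

    def membership(self, grid: VoxelGrid) -> list[np.ndarray]:
        """Per sphere, indices (into the in-mask axis) of the voxels inside."""
        return [np.flatnonzero(s.contains(grid.coords_mm)) for s in self.spheres]


@dataclass
class GroupFactorSolution:
    """Second-level (group) factor solution with voxel traceback."""

    group: str
    scores: np.ndarray                  # (16, 4) group factor item scores
    loadings: np.ndarray                # (n_participants*7, 4)
    column_ids: list[tuple[str, int]]   # (participant_id, l1 factor) per column
    assignment: np.ndarray              # (n_columns,) group factor or -1
    variance_explained: np.ndarray      # (4,) percent of variable variance
    traced: list[dict]                  # per factor: pooled voxel provenance
    grid: VoxelGrid

    @property
    def n_factors(self) -> int:
        return self.scores.shape[1]


def _pca_varimax_scores(X: np.ndarray, n_factors: int):
    """Shared extraction used at both levels.

    X is observations x variables.  Returns (rotated loadings, standardized
    regression-method scores, eigenvalues).  Constant variables must already
    be removed.
    """
    n_obs, n_var = X.shape
    R = np.corrcoef(X, rowvar=False)
    ev, vec = np.linalg.eigh(R)
    order = np.argsort(ev)[::-1]
    ev, vec = ev[order], vec[:, order]
    ev_c = np.clip(ev, 0.0, None)
    L = vec[:, :n_factors] * np.sqrt(ev_c[:n_factors])
    Lr, _ = varimax(L)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    # regression-method factor scores; R is rank-deficient when n_obs < n_var,
    # so invert only the numerically meaningful part of the spectrum
    W = np.linalg.pinv(R, rcond=1e-6) @ Lr
    F = Z @ W
    sd = F.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    F = F / sd
    return Lr, F, ev


def _assign(loadings: np.ndarray, threshold: float) -> np.ndarray:
    """Row -> factor with the maximal |loading| when above threshold, else -1."""
    best = np.argmax(np.abs(loadings), axis=1)
    val = np.abs(loadings)[np.arange(loadings.shape[0]), best]
    out = np.where(val >= threshold, best, -1)
    return out.astype(int)


def fit_first_level(d: ActivationDataset,
                    sel: VoxelSelection,
                    n_factors: int = 7,
                    loading_threshold: float = 0.4) -> FactorSolutionL1:
    """Factor one participant's selected voxels.

    The tensor is averaged over blocks to a 16 x n_selected matrix; the voxel
    correlation matrix over the 16 items is factored by principal-component
    extraction, varimax-rotated, and item scores obtained by the regression
    method.  Each voxel is linked to the factor with its maximal |loading|
    when that exceeds ``loading_threshold``.
    """
    if n_factors > N_ITEMS - 1:
        raise ValueError("cannot extract more factors than items - 1")
    X = d.block_mean()[:, sel.indices]           # (16, n_selected)
    sd = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < X.shape[1]:
        warnings.warn(f"{X.shape[1] - len(kept)} constant voxel(s) excluded "
                      "from the correlation matrix")
    Lr, F, ev = _pca_varimax_scores(X[:, kept], n_factors)
    assignment = np.full(X.shape[1], -1, dtype=int)
    assignment[kept] = _assign(Lr, loading_threshold)
    full_load = np.zeros((X.shape[1], n_factors))
    full_load[kept] = Lr
    return FactorSolutionL1(participant_id=d.participant_id,
                            loadings=full_load, scores=F,
                            assignment=assignment, eigenvalues=ev,
                            selection=sel, kept=kept)


def fit_group_level(solutions: list[FactorSolutionL1],
                    grid: VoxelGrid,
                    group: str = "",
                    n_factors: int = 4,
                    loading_threshold: float = 0.4) -> GroupFactorSolution:
    """Factor the pooled first-level score vectors of a group.

    The variables are all participants' first-level factor score vectors
    (n_participants * 7 columns over 16 item observations), processed with the
    same extraction/rotation/score method as level 1.  Every first-level
    factor is assigned to the group factor with its maximal |loading| above
    threshold; a group factor's traced voxels are the union, over its assigned
    first-level factors, of the voxels those factors were linked to.
    """
    if len(solutions) < 2:
        raise ValueError("group-level FA needs at least 2 participants")
    cols, ids = [], []
    for s in solutions:
        for j in range(s.scores.shape[1]):
            cols.append(s.scores[:, j])
            ids.append((s.participant_id, j))
    X = np.column_stack(cols)                    # (16, n*7)
    Lr, F, _ = _pca_varimax_scores(X, n_factors)
    assignment = _assign(Lr, loading_threshold)

    sols = {s.participant_id: s for s in solutions}
    traced = []
    for g in range(n_factors):
        vox_idx, weights, signs, pids = [], [], [], []
        for c in np.flatnonzero(assignment == g):
            pid, j = ids[c]
            s = sols[pid]
            fac_load = Lr[c, g]
            members = np.flatnonzero(s.assignment == j)
            for m in members:
                vox_idx.append(s.selection.indices[m])
                w = abs(s.loadings[m, j]) * abs(fac_load)
                weights.append(w)
                signs.append(np.sign(s.loadings[m, j]) * np.sign(fac_load))
                pids.append(pid)
        traced.append({
            "voxel_indices": np.array(vox_idx, dtype=int),
            "weights": np.array(weights, dtype=float),
            "signs": np.array(signs, dtype=float),
            "participants": pids,
        })
    var_expl = 100.0 * (Lr ** 2).sum(axis=0) / X.shape[1]
    return GroupFactorSolution(group=group, scores=F, loadings=Lr,
                               column_ids=ids, assignment=assignment,
                               variance_explained=var_expl, traced=traced,
                               grid=grid)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def cluster_to_spheres(voxel_indices: np.ndarray,
                       grid: VoxelGrid,
                       weights: np.ndarray | None = None,
                       max_spheres: int = 6,
                       factor: str = "",
                       source_group: str = "") -> SphereSet:
    """Cluster traced voxels into spheres.

    Pooled voxel entries (with multiplicity across participants) are grouped
    into connected components under 26-connectivity on the grid.  Components
    are ranked by member count (ties by summed |loading| weight); the top
    ``max_spheres`` become spheres with center at the member centroid and
    radius = max centroid-to-member distance + half the largest voxel size.
    """
    voxel_indices = np.asarray(voxel_indices, dtype=int)
    if voxel_indices.size == 0:
        warnings.warn("empty voxel set: returning an empty SphereSet")
        return SphereSet(spheres=[])
    if weights is None:
        weights = np.ones(voxel_indices.shape[0])

    occ = np.zeros(grid.shape, dtype=bool)
    ijk = grid.mask_indices[voxel_indices]
    occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    labels, n_comp = ndimage.label(occ, structure=_STRUCT_26)
    comp_of_entry = labels[ijk[:, 0], ijk[:, 1], ijk[:, 2]]

    stats = []
    for c in range(1, n_comp + 1):
        members = np.flatnonzero(comp_of_entry == c)
        stats.append((c, len(members), float(weights[members].sum())))
    stats.sort(key=lambda t: (-t[1], -t[2], t[0]))

    half_vox = float(grid.voxel_sizes.max()) / 2.0
    coords = grid.coords_mm[voxel_indices]
    spheres = []
    for c, count, _w in stats[:max_spheres]:
        members = np.flatnonzero(comp_of_entry == c)
        pts = coords[members]
        center = pts.mean(axis=0)
        radius = float(np.linalg.norm(pts - center, axis=1).max()) + half_vox
        spheres.append(Sphere(center_mm=center, radius_mm=radius,
                              factor=factor, source_group=source_group,
                              n_members=count))
    return SphereSet(spheres=spheres)


def factor_sphere_sets(sol: GroupFactorSolution,
                       max_spheres: int = 6,
                       factor_names: list[str] | None = None) -> list[SphereSet]:
    """One SphereSet per group factor, from that factor's traced voxels."""
    out = []
    for g in range(sol.n_factors):
        tr = sol.traced[g]
        name = factor_names[g] if factor_names else f"GF{g + 1}"
        out.append(cluster_to_spheres(tr["voxel_indices"], sol.grid,
                                      weights=tr["weights"],
                                      max_spheres=max_spheres,
                                      factor=name, source_group=sol.group))
    return out


@dataclass
class FactorMatch:
    """One-to-one matching of recovered factors to reference templates."""

    assignment: list[int]        # reference column per recovered factor
    correlations: np.ndarray     # signed r per recovered factor
    names: list[str] = field(default_factory=list)

    def by_name(self) -> dict[str, tuple[int, float]]:
        """reference name -> (recovered factor index, signed r)."""
        return {self.names[ref]: (i, float(self.correlations[i]))
                for i, ref in enumerate(self.assignment)}


def match_factors(recovered_scores: np.ndarray,
                  reference_scores: np.ndarray,
                  reference_names: list[str] | None = None) -> FactorMatch:
    """Assign recovered factors to reference templates, maximizing the total
    |score correlation| exhaustively over all injective assignments."""
    R = np.asarray(recovered_scores, dtype=float)
    T = np.asarray(reference_scores, dtype=float)
    if R.shape[0] != T.shape[0]:
        raise ValueError("recovered and reference scores must share the item axis")
    k, m = R.shape[1], T.shape[1]
    if k > m:
        raise ValueError("more recovered factors than reference templates")
    C = np.corrcoef(R.T, T.T)[:k, k:]            # (k, m) signed correlations
    best, best_val = None, -np.inf
    for perm in itertools.permutations(range(m), k):
        val = sum(abs(C[i, p]) for i, p in enumerate(perm))
        if val > best_val:
            best_val, best = val, perm
    corr = np.array([C[i, p] for i, p in enumerate(best)])
    names = reference_names or [f"ref{j}" for j in range(m)]
    return FactorMatch(assignment=list(best), correlations=corr, names=names)
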