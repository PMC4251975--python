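"""Factor extraction, varimax, clustering and template matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

import neurosem as ns
from neurosem.io_core import ActivationDataset, VoxelGrid, canonical_item_set
from neurosem.factor_pipeline import (cluster_to_spheres, fit_first_level,
                                      fit_group_level, kaiser_count,
                                      match_factors, varimax,
                                      varimax_criterion)
from neurosem.voxel_selection import select_stable_voxels


@pytest.mark.parametrize("ev, expected", [
    ([3.2, 1.5, 1.01, 0.99, 0.3], 3),
    ([0.9, 0.5, 0.1], 0),
    (np.ones(8), 0),          # strict inequality at the boundary
])
def test_kaiser_count(ev, expected):
    assert kaiser_count(ev) == expected


def test_kaiser_count_empty_raises():
    with pytest.raises(ValueError):
        kaiser_count([])


def test_varimax_fixed_point_on_perfect_simple_structure():
    L = np.zeros((6, 2))
    L[:3, 0] = [0.9, 0.8, 0.7]
    L[3:, 1] = [0.85, 0.75, 0.6]
    Lr, R = varimax(L)
    # unchanged up to column permutation and sign
    C = np.abs(L.T @ Lr)
    perm = np.argmax(C, axis=1)
    assert sorted(perm) == [0, 1]
    np.testing.assert_allclose(np.abs(Lr[:, perm]), np.abs(L), atol=1e-8)
    np.testing.assert_allclose(R.T @ R, np.eye(2), atol=1e-10)


def test_varimax_matches_grid_search_oracle_two_factors():
    """For 2 factors the optimal orthogonal rotation is a single angle;
    exhaustive search at 1e-4 resolution bounds the achievable criterion."""
    rng = np.random.default_rng(0)
    L = rng.standard_normal((10, 2))
    Lr, _ = varimax(L, normalize=False)
    got = varimax_criterion(Lr, normalize=False)
    best = -np.inf
    for th in np.arange(0.0, np.pi / 2, 1e-4):
        c, s = np.cos(th), np.sin(th)
        R = np.array([[c, -s], [s, c]])
        best = max(best, varimax_criterion(L @ R, normalize=False))
    assert got == pytest.approx(best, abs=1e-4)


def test_varimax_criterion_never_decreases_with_more_iterations():
    rng = np.random.default_rng(1)
    L = rng.standard_normal((20, 4))
    vals = []
    for it in (1, 2, 3, 5, 10, 50):
        with np.errstate(all="ignore"):
            import warnings as w
            with w.catch_warnings():
                w.simplefilter("ignore")
                Lr, _ = varimax(L, max_iter=it)
        vals.append(varimax_criterion(Lr))
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


@settings(max_examples=15, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 32 - 1))
def test_varimax_rotation_is_orthonormal(seed):
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((12, 3))
    Lr, R = varimax(L)
    np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-8)
    np.testing.assert_allclose(np.abs(Lr), np.abs((L / np.sqrt((L**2).sum(1, keepdims=True))) @ R
                               * np.sqrt((L**2).sum(1, keepdims=True))), atol=1e-8)


def _toy_two_factor_dataset(grid, seed=0):
    """30-voxel dataset driven by two orthogonal planted score vectors."""
    rng = np.random.default_rng(seed)
    s1 = np.tile([1.0, -1.0], 8)
    s2 = np.repeat([1.0, -1.0], 8)
    s1, s2 = s1 - s1.mean(), s2 - s2.mean()
    V = grid.n_voxels
    load = np.zeros((2, V))
    load[0, :15] = rng.uniform(0.8, 1.2, 15)
    load[1, 15:30] = rng.uniform(0.8, 1.2, 15)
    signal = s1[:, None] * load[0] + s2[:, None] * load[1]
    noise = 1e-4 * rng.standard_normal((16, 6, V))
    data = signal[:, None, :] + noise
    return ActivationDataset("toy", data, grid, canonical_item_set()), (s1, s2)


def test_first_level_recovers_planted_orthogonal_factors(tiny_grid):
    d, (s1, s2) = _toy_two_factor_dataset(tiny_grid)
    stab = ns.voxel_stability(d)
    sel = select_stable_voxels(stab, [("all", np.ones(tiny_grid.n_voxels, bool))],
                               tiny_grid, total=30)
    sol = fit_first_level(d, sel, n_factors=2)
    m = match_factors(sol.scores, np.column_stack([s1, s2]), ["s1", "s2"])
    assert all(abs(r) >= 0.99 for r in m.correlations)
    # voxels split between the two factors
    assert set(sol.assignment[:30]) <= {0, 1}


def test_first_level_scale_invariance(tiny_grid):
    d, _ = _toy_two_factor_dataset(tiny_grid)
    stab = ns.voxel_stability(d)
    sel = select_stable_voxels(stab, [("all", np.ones(tiny_grid.n_voxels, bool))],
                               tiny_grid, total=30)
    sol1 = fit_first_level(d, sel, n_factors=2)
    d2 = ActivationDataset("x", d.data.copy(), d.grid, d.items)
    scaled = sel.indices[0]
    d2.data[:, :, scaled] *= 2.0
    sol2 = fit_first_level(d2, sel, n_factors=2)
    np.testing.assert_allclose(np.abs(sol1.loadings[0]),
                               np.abs(sol2.loadings[0]), atol=1e-6)


def test_first_level_pure_noise_assigns_fewer_voxels_than_signal(tiny_grid):
    """Linked-voxel rate on pure noise stays well below the rate on strongly
    structured data (Monte-Carlo null)."""
    rates = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        d = ActivationDataset("n", rng.standard_normal((16, 6, tiny_grid.n_voxels)),
                              tiny_grid, canonical_item_set())
        stab = ns.voxel_stability(d)
        sel = select_stable_voxels(stab, [("all", np.ones(tiny_grid.n_voxels, bool))],
                                   tiny_grid, total=30)
        sol = fit_first_level(d, sel, n_factors=2)
        rates.append(np.mean(sol.assignment >= 0))
    d, _ = _toy_two_factor_dataset(tiny_grid)
    stab = ns.voxel_stability(d)
    sel = select_stable_voxels(stab, [("all", np.ones(tiny_grid.n_voxels, bool))],
                               tiny_grid, total=30)
    sol = fit_first_level(d, sel, n_factors=2)
    signal_rate = np.mean(sol.assignment[:30] >= 0)
    # small-sample noise loadings are sizeable, but linked-voxel rates stay
    # clearly below the (near-total) rate on structured data
    assert np.mean(rates) < signal_rate - 0.2


def test_group_level_degenerate_identical_participants(tiny_grid):
    """If every participant has the same first-level solution, the group
    factors reproduce the first-level scores up to sign/permutation."""
    d, (s1, s2) = _toy_two_factor_dataset(tiny_grid)
    stab = ns.voxel_stability(d)
    sel = select_stable_voxels(stab, [("all", np.ones(tiny_grid.n_voxels, bool))],
                               tiny_grid, total=30)
    sols = []
    for pid in ("p1", "p2", "p3"):
        s = fit_first_level(d, sel, n_factors=2)
        s.participant_id = pid
        sols.append(s)
    g = fit_group_level(sols, tiny_grid, group="g", n_factors=2)
    m = match_factors(g.scores, sols[0].scores, ["f0", "f1"])
    assert all(abs(r) > 0.999 for r in m.correlations)


def test_group_level_requires_two_participants(tiny_grid):
    d, _ = _toy_two_factor_dataset(tiny_grid)
    stab = ns.voxel_stability(d)
    sel = select_stable_voxels(stab, [("all", np.ones(tiny_grid.n_voxels, bool))],
                               tiny_grid, total=30)
    sol = fit_first_level(d, sel, n_factors=2)
    with pytest.raises(ValueError, match="2 participants"):
        fit_group_level([sol], tiny_grid)


def test_two_adjacent_voxels_make_one_sphere(tiny_grid):
    # voxels at (0,0,0) and (4,0,0) mm: center (2,0,0), radius 2+2=4
    idx = [int(np.flatnonzero((tiny_grid.coords_mm == c).all(axis=1))[0])
           for c in ([0, 0, 0], [4, 0, 0])]
    ss = cluster_to_spheres(np.array(idx), tiny_grid)
    assert len(ss) == 1
    np.testing.assert_allclose(ss.spheres[0].center_mm, [2, 0, 0])
    assert ss.spheres[0].radius_mm == pytest.approx(4.0)


def test_two_distant_blobs_make_two_spheres():
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    grid = VoxelGrid(affine=affine, mask=np.ones((12, 4, 4), bool))
    coords = grid.coords_mm
    blob1 = np.flatnonzero(coords[:, 0] <= 4)
    blob2 = np.flatnonzero(coords[:, 0] >= 40)
    ss = cluster_to_spheres(np.concatenate([blob1, blob2]), grid)
    assert len(ss) == 2


def test_empty_voxel_set_warns_and_returns_empty(tiny_grid):
    with pytest.warns(UserWarning, match="empty"):
        ss = cluster_to_spheres(np.array([], dtype=int), tiny_grid)
    assert len(ss) == 0


def _flood_fill_components(ijk_set):
    """Brute-force 26-connectivity flood fill over a set of voxel indices."""
    remaining = set(map(tuple, ijk_set))
    comps = []
    while remaining:
        seed = remaining.pop()
        comp, frontier = {seed}, [seed]
        while frontier:
            x, y, z = frontier.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        nb = (x + dx, y + dy, z + dz)
                        if nb in remaining:
                            remaining.remove(nb)
                            comp.add(nb)
                            frontier.append(nb)
        comps.append(comp)
    return comps


def test_cluster_partition_equals_flood_fill_oracle():
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    grid = VoxelGrid(affine=affine, mask=np.ones((8, 8, 8), bool))
    rng = np.random.default_rng(4)
    chosen = rng.choice(grid.n_voxels, size=60, replace=False)
    ss = cluster_to_spheres(chosen, grid, max_spheres=1000)
    oracle = _flood_fill_components(grid.mask_indices[chosen])
    assert len(ss) == len(oracle)
    assert sorted(s.n_members for s in ss.spheres) == sorted(len(c) for c in oracle)


def test_match_factors_identity_and_sign_flip():
    rng = np.random.default_rng(0)
    ref = rng.standard_normal((16, 4))
    m = match_factors(ref, ref, list("abcd"))
    assert m.assignment == [0, 1, 2, 3]
    np.testing.assert_allclose(m.correlations, 1.0)
    m2 = match_factors(-ref, ref, list("abcd"))
    assert m2.assignment == [0, 1, 2, 3]
    np.testing.assert_allclose(m2.correlations, -1.0)


def test_match_factors_agrees_with_assignment_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        A = rng.standard_normal((16, 4))
        B = rng.standard_normal((16, 4))
        m = match_factors(A, B)
        C = np.abs(np.corrcoef(A.T, B.T)[:4, 4:])
        rows, cols = linear_sum_assignment(-C)   # independent optimal matcher
        assert C[rows, cols].sum() == pytest.approx(
            sum(abs(c) for c in m.correlations), abs=1e-12)
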