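"""Feature extraction, feature selection, GNB and the decoding protocols."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neurosem as ns
from neurosem.io_core import CONTROL
from neurosem.factor_pipeline import Sphere, SphereSet
from neurosem.classification import (GnbModel, gnb_scores, gnb_train,
                                     rank_accuracy,
                                     select_discriminative_features,
                                     sphere_feature_rows,
                                     within_participant_item_classification,
                                     across_participant_item_classification,
                                     loo_group_classification)
from neurosem.pipeline import derive_cohort
from neurosem.synthetic_cohort import PLANTED_SELF_SPHERE, simulate_participant

from conftest import noise_free_config


# --------------------------- features ------------------------------------

def test_zscore_of_123_profile():
    profile = np.array([[1.0], [2.0], [3.0]])          # 3 items, 1 voxel
    rows = sphere_feature_rows(profile, np.array([1.0]), [np.array([0])],
                               n_voxels=1)
    np.testing.assert_allclose(rows[0], [-1.0, 0.0, 1.0])


@settings(max_examples=15, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 32 - 1))
def test_feature_rows_have_zero_mean_unit_sample_sd(seed):
    rng = np.random.default_rng(seed)
    profile = rng.standard_normal((16, 40))
    stab = rng.uniform(-1, 1, 40)
    membership = [rng.choice(40, size=8, replace=False) for _ in range(3)]
    rows = sphere_feature_rows(profile, stab, membership)
    np.testing.assert_allclose(rows.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(rows.std(axis=1, ddof=1), 1.0, atol=1e-12)


def test_noise_free_self_sphere_feature_matches_template(coarse_grid):
    """sigma=0 control-like participant: the posterior-midline sphere feature
    equals the z-scored self score template."""
    cfg = noise_free_config(n_per_group=1)
    datasets, _, truth = ns.simulate_cohort(cfg, seed=0, grid=coarse_grid)
    d = datasets[1]
    feats = ns.sphere_features(d, SphereSet([PLANTED_SELF_SPHERE]), n_voxels=5)
    s = truth.templates["self"].scores
    z = (s - s.mean()) / s.std(ddof=1)
    r = np.corrcoef(feats, z)[0, 1]
    assert abs(r) > 0.999


# ----------------------- feature selection -------------------------------

def test_top_gap_feature_selected():
    X = np.array([[0.0, 0.0], [2.0, 0.1], [0.0, 0.0], [2.0, 0.1]])
    y = np.array(["a", "b", "a", "b"])
    assert list(select_discriminative_features(X, y, k=1)) == [0]


def test_selection_matches_sort_oracle_and_label_symmetry():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((20, 50))
    y = np.array(["a"] * 10 + ["b"] * 10)
    sel = select_discriminative_features(X, y, k=12)
    gap = np.abs(X[:10].mean(0) - X[10:].mean(0))
    oracle = sorted(sorted(range(50), key=lambda j: (-gap[j], j))[:12])
    assert list(sel) == oracle
    y_swapped = np.where(y == "a", "b", "a")
    assert list(select_discriminative_features(X, y_swapped, k=12)) == oracle


def test_selection_k_too_large_raises():
    X = np.zeros((4, 3))
    y = np.array(["a", "b", "a", "b"])
    with pytest.raises(ValueError, match="exceeds"):
        select_discriminative_features(X, y, k=4)


# ------------------------------- GNB --------------------------------------

def test_gnb_reproduces_class_means_and_priors():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((30, 4))
    y = np.array([0] * 10 + [1] * 20)
    m = gnb_train(X, y, variance_mode="per_class")
    np.testing.assert_allclose(m.means[0], X[:10].mean(0))
    np.testing.assert_allclose(m.means[1], X[10:].mean(0))
    np.testing.assert_allclose(m.priors, [1 / 3, 2 / 3])


def test_gnb_posterior_half_at_midpoint():
    X = np.array([[0.0], [0.0], [2.0], [2.0]])
    y = np.array(["a", "a", "b", "b"])
    m = gnb_train(X, y, variance_mode="pooled", variance_floor=1e-12)
    # zero within-class variance -> floored; symmetric at x=1 regardless
    s = gnb_scores(m, np.array([1.0]))
    p = np.exp(s - s.max())
    p /= p.sum()
    np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)


def test_gnb_scores_match_closed_form_densities():
    """Hand-computed Gaussian log densities, 1e-10 relative tolerance."""
    X = np.array([[0.0, 1.0], [0.2, 0.8], [2.0, -1.0], [2.2, -0.6]])
    y = np.array(["a", "a", "b", "b"])
    for mode in ("pooled", "per_class"):
        m = gnb_train(X, y, variance_mode=mode)
        x = np.array([0.7, 0.3])
        got = gnb_scores(m, x)
        for c in range(2):
            expected = np.log(0.5)
            for f in range(2):
                v = m.variances[c, f]
                expected += (-0.5 * np.log(2 * np.pi * v)
                             - (x[f] - m.means[c, f]) ** 2 / (2 * v))
            assert got[c] == pytest.approx(expected, rel=1e-10)


def test_gnb_matches_sklearn_per_class_variance():
    sklearn = pytest.importorskip("sklearn.naive_bayes")
    rng = np.random.default_rng(3)
    X = rng.standard_normal((40, 6))
    y = rng.integers(0, 3, 40)
    m = gnb_train(X, y, variance_mode="per_class", variance_floor=0.0)
    ref = sklearn.GaussianNB(var_smoothing=1e-300).fit(X, y)
    got = gnb_scores(m, X)
    want = ref.predict_log_proba(X)
    got_norm = got - np.log(np.exp(got).sum(axis=1, keepdims=True))
    np.testing.assert_allclose(got_norm, want, atol=1e-8)


def test_gnb_translation_invariance_of_argmax():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((20, 3))
    y = np.array([0] * 10 + [1] * 10)
    m = gnb_train(X, y)
    x = rng.standard_normal(3)
    s1 = gnb_scores(m, x)
    m2 = GnbModel(classes=m.classes, priors=m.priors,
                  means=m.means + 5.0, variances=m.variances)
    s2 = gnb_scores(m2, x + 5.0)
    assert np.argmax(s1) == np.argmax(s2)
    np.testing.assert_allclose(s1, s2, atol=1e-9)


def test_gnb_errors_and_fallback():
    X = np.array([[0.0], [1.0], [2.0]])
    with pytest.raises(ValueError, match="at least one"):
        gnb_train(X[:0], np.array([], dtype=int))
    with pytest.warns(UserWarning, match="single exemplar"):
        m = gnb_train(X, np.array([0, 0, 1]), variance_mode="per_class")
    assert m.variances[0, 0] == m.variances[1, 0]  # pooled fallback
    m2 = gnb_train(X, np.array([0, 0, 1]))
    with pytest.raises(ValueError, match="dimension"):
        gnb_scores(m2, np.zeros(2))


# --------------------------- rank accuracy ---------------------------------

def test_rank_accuracy_extremes_and_ties():
    s = np.arange(16.0)
    assert rank_accuracy(s, 15) == 1.0
    assert rank_accuracy(s, 0) == 0.0
    tied = np.zeros(16)
    assert rank_accuracy(tied, 4) == pytest.approx(0.5)


def test_rank_accuracy_uniform_scorer_mean_half():
    # exact enumeration over the 16 possible ranks
    vals = [(16 - r) / 15 for r in range(1, 17)]
    assert np.mean(vals) == pytest.approx(0.5)
    # Monte Carlo with random scores, 1e5 draws
    rng = np.random.default_rng(0)
    draws = [rank_accuracy(rng.standard_normal(16), 0) for _ in range(100_000)]
    assert np.mean(draws) == pytest.approx(0.5, abs=0.01)


# ------------------------- decoding protocols ------------------------------

def _planted_sphere_set(truth):
    spheres = []
    for name, t in truth.templates.items():
        for c in t.centers:
            spheres.append(Sphere(center_mm=np.asarray(c), radius_mm=8.0,
                                  factor=name))
    return SphereSet(spheres)


def test_noise_free_within_participant_decoding_is_perfect(coarse_grid):
    cfg = noise_free_config(n_per_group=1)
    datasets, _, truth = ns.simulate_cohort(cfg, seed=0, grid=coarse_grid)
    ss = _planted_sphere_set(truth)
    mean_acc, table = within_participant_item_classification(datasets[1], ss)
    assert mean_acc == 1.0
    assert table.shape == (15, 16)


def test_clone_cohort_across_participant_decoding_is_perfect(coarse_grid):
    """Identical participants (sigma=0, same seed) decode each other exactly."""
    cfg = noise_free_config(n_per_group=1)
    datasets, metas, truth = ns.simulate_cohort(cfg, seed=0, grid=coarse_grid)
    pt = truth.participants[1]
    clones = []
    for pid in ("c1", "c2", "c3"):
        d = simulate_participant(truth, pt, coarse_grid)
        d.participant_id = pid
        clones.append(d)
    regions = [("all", np.ones(coarse_grid.n_voxels, bool))]
    derived = derive_cohort(clones, regions=regions, total_voxels=50)
    ss = _planted_sphere_set(truth)
    acc = across_participant_item_classification(derived, ss)
    np.testing.assert_allclose(acc, 1.0)


def test_label_permuted_training_sits_at_chance(coarse_cohort):
    datasets, metas, truth = coarse_cohort
    ss = _planted_sphere_set(truth)
    rng = np.random.default_rng(0)
    accs = [within_participant_item_classification(
        d, ss, permute_labels_rng=rng)[0] for d in datasets[:3]]
    assert abs(np.mean(accs) - 0.5) < 0.08


def test_increasing_noise_does_not_help_decoding(coarse_grid):
    """Paired seeds, sigma grid: expected accuracy is monotone non-increasing."""
    means = []
    for sigma in (0.5, 2.0, 8.0):
        cfg = ns.CohortConfig(n_per_group=2, noise_sigma=sigma)
        datasets, _, truth = ns.simulate_cohort(cfg, seed=11, grid=coarse_grid)
        ss = _planted_sphere_set(truth)
        means.append(np.mean([
            within_participant_item_classification(d, ss)[0]
            for d in datasets]))
    assert means[0] >= means[1] - 0.02 >= means[2] - 0.04


def test_loo_hygiene_left_out_label_cannot_leak(coarse_cohort):
    """Flipping the left-out participant's group label must not change that
    fold's prediction: the training side never sees it."""
    from dataclasses import replace
    datasets, metas, _ = coarse_cohort
    res = loo_group_classification(datasets, metas, ks=(20,))
    flipped = list(metas)
    flipped[0] = replace(metas[0], group=CONTROL)
    res2 = loo_group_classification(datasets, flipped, ks=(20,))
    assert res.predictions[20][0] == res2.predictions[20][0]
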