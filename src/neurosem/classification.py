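"""Gaussian-naive-Bayes decoding with factor-sphere features.

Three protocols:

* leave-one-participant-out **group-membership** classification (autism-like
  vs control-like), with per-fold two-level factor analyses, 36 semantic
  factor spheres, 576 z-scored sphere-item features and top-k
  group-mean-difference feature selection;
* **within-participant** decoding of the 16 items, training on 4 of the 6
  presentation blocks and testing on the mean of the held-out 2, over all 15
  block-pair folds, with 24 factor spheres;
* **across-participant** decoding of the 16 items, leave-one-participant-out
  within a group, from block-averaged 24-sphere exemplars.

Decoding performance is summarized as normalized rank accuracy,
(N - rank)/(N - 1): 1 when the true item is top-ranked, 0.5 at chance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io_core import ActivationDataset, ParticipantMeta, N_BLOCKS, N_ITEMS
from .factor_pipeline import SphereSet
from .pipeline import (ParticipantDerived, derive_cohort, group_solution,
                       semantic_sphere_set)
from .voxel_selection import voxel_stability

__all__ = [
    "sphere_feature_rows",
    "sphere_features",
    "select_discriminative_features",
    "GnbModel",
    "gnb_train",
    "gnb_scores",
    "rank_accuracy",
    "GroupClassificationResult",
    "loo_group_classification",
    "within_participant_item_classification",
    "across_participant_item_classification",
]


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    """Z-score each row across items with the sample (ddof=1) sd."""
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


def sphere_feature_rows(profile: np.ndarray,
                        stability: np.ndarray,
                        membership: list[np.ndarray],
                        n_voxels: int = 5,
                        warn_small: bool = False) -> np.ndarray:
    """(n_spheres, 16) z-scored sphere profiles.

    For each sphere: average the item profiles of its ``n_voxels`` most
    stable in-sphere voxels, then z-score across the 16 items.  Spheres with
    fewer than ``n_voxels`` voxels use all of them.
    """
    rows = np.zeros((len(membership), profile.shape[0]))
    for s, inside in enumerate(membership):
        if inside.size == 0:
            raise ValueError(f"sphere {s} contains no in-mask voxel")
        if inside.size < n_voxels and warn_small:
            warnings.warn(f"sphere {s} has only {inside.size} voxels; using all")
        take = inside[np.argsort(-stability[inside], kind="stable")[:n_voxels]]
        rows[s] = profile[:, take].mean(axis=1)
    return _zscore_rows(rows)


def sphere_features(d: ActivationDataset,
                    spheres: SphereSet,
                    blocks=None,
                    n_voxels: int = 5) -> np.ndarray:
    """Flat 16*n_spheres feature vector for one participant.

    Stability and the item profiles are both computed from the stated block
    subset (default: all 6 blocks).
    """
    blocks = list(blocks) if blocks is not None else list(range(N_BLOCKS))
    stab = voxel_stability(d, blocks)
    profile = d.data[:, blocks, :].mean(axis=1)
    membership = spheres.membership(d.grid)
    return sphere_feature_rows(profile, stab, membership,
                               n_voxels=n_voxels).ravel()


def select_discriminative_features(train: np.ndarray,
                                   labels: np.ndarray,
                                   k: int = 115) -> np.ndarray:
    """Top-k columns by |difference of the two class means| on training rows.

    Ties are broken by column index.  Label swaps leave the result unchanged.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("feature selection requires exactly two classes")
    if k > train.shape[1]:
        raise ValueError(f"k={k} exceeds the {train.shape[1]} available features")
    gap = np.abs(train[labels == classes[0]].mean(axis=0)
                 - train[labels == classes[1]].mean(axis=0))
    order = np.lexsort((np.arange(train.shape[1]), -gap))
    return np.sort(order[:k])


@dataclass
class GnbModel:
    """Per-class Gaussian naive Bayes parameters (variances floored)."""

    classes: np.ndarray
    priors: np.ndarray            # (C,)
    means: np.ndarray             # (C, F)
    variances: np.ndarray         # (C, F)


def gnb_train(features: np.ndarray,
              labels: np.ndarray,
              variance_mode: str = "pooled",
              variance_floor: float = 1e-6) -> GnbModel:
    """Fit a Gaussian naive Bayes model.

    ``pooled`` shares one per-feature variance across classes (mean squared
    deviation from the own-class mean over all exemplars); ``per_class``
    estimates each class separately and falls back to pooled (with a warning)
    when some class has a single exemplar.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    counts = np.bincount(y, minlength=len(classes))
    if (counts < 1).any():
        raise ValueError("every class needs at least one exemplar")
    if variance_mode == "per_class" and (counts < 2).any():
        warnings.warn("a class has a single exemplar; falling back to pooled variance")
        variance_mode = "pooled"
    if variance_mode not in ("pooled", "per_class"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    C, F = len(classes), X.shape[1]
    means = np.vstack([X[y == c].mean(axis=0) for c in range(C)])
    resid_sq = (X - means[y]) ** 2
    if variance_mode == "pooled":
        v = resid_sq.mean(axis=0)
        variances = np.tile(v, (C, 1))
    else:
        variances = np.vstack([resid_sq[y == c].mean(axis=0) for c in range(C)])
    variances = np.maximum(variances, variance_floor)
    priors = counts / counts.sum()
    return GnbModel(classes=classes, priors=priors, means=means,
                    variances=variances)


def gnb_scores(model: GnbModel, x: np.ndarray) -> np.ndarray:
    """Per-class log posteriors (up to the shared evidence constant).

    Accepts a single feature vector (F,) or a batch (N, F); returns (C,) or
    (N, C).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(f"feature dimension {X.shape[1]} does not match the "
                         f"model's {model.means.shape[1]}")
    diff = X[:, None, :] - model.means[None, :, :]          # (N, C, F)
    log_like = -0.5 * ((diff ** 2 / model.variances).sum(axis=2)
                       + np.log(2.0 * np.pi * model.variances).sum(axis=1))
    out = np.log(model.priors)[None, :] + log_like
    return out[0] if single else out


def rank_accuracy(scores: np.ndarray, true_class: int,
                  n_classes: int | None = None) -> float:
    """Normalized rank accuracy (n - rank)/(n - 1), ties -> average rank."""
    scores = np.asarray(scores, dtype=float)
    n = n_classes or scores.shape[0]
    if not 0 <= true_class < scores.shape[0]:
        raise ValueError("true class outside the score vector")
    r = rankdata(-scores, method="average")[true_class]
    return float((n - r) / (n - 1))


# ---------------------------------------------------------------------------
# protocol 1: leave-one-participant-out group-membership classification
# ---------------------------------------------------------------------------

@dataclass
class GroupClassificationResult:
    participant_ids: list[str]
    true_groups: list[str]
    predictions: dict[int, list[str]]      # k -> per-fold predicted group
    n_features_available: list[int]        # per fold
    sphere_counts: list[int]               # per fold

    def accuracy(self, k: int) -> float:
        pred = self.predictions[k]
        hits = sum(p == t for p, t in zip(pred, self.true_groups))
        return hits / len(self.true_groups)

    def n_correct(self, k: int) -> int:
        return sum(p == t for p, t in zip(self.predictions[k], self.true_groups))


def _cohort_feature_matrix(derived: list[ParticipantDerived],
                           spheres: SphereSet,
                           n_voxels: int = 5) -> np.ndarray:
    grid = derived[0].dataset.grid
    membership = spheres.membership(grid)
    return np.vstack([
        sphere_feature_rows(p.profile, p.stability, membership,
                            n_voxels=n_voxels).ravel()
        for p in derived])


def loo_group_classification(datasets: list[ActivationDataset],
                             metas: list[ParticipantMeta],
                             ks=(115,),
                             n_voxels: int = 5,
                             derived: list[ParticipantDerived] | None = None,
                             variance_mode: str = "per_class",
                             ) -> GroupClassificationResult:
    """Full leave-one-participant-out group classification.

    Each fold refits both groups' two-level factor analyses on the 33
    training participants only, identifies each group's 3 semantic factors
    (excluding the word-length factor), builds the union of their spheres
    (up to 36), computes z-scored sphere-item features for *all* participants
    (the protocol withholds the test participant's label, not their data),
    selects the top-k features on training rows, trains a Gaussian naive
    Bayes classifier and classifies the left-out participant.  Several k are
    evaluated per fold at no extra factor-analysis cost.
    """
    if derived is None:
        derived = derive_cohort(datasets, metas)
    items = datasets[0].items
    groups = sorted({m.group for m in metas})
    if len(groups) != 2:
        raise ValueError("group classification needs exactly two groups")
    by_group = {g: [p for p, m in zip(derived, metas) if m.group == g]
                for g in groups}

    ids = [d.participant_id for d in datasets]
    true = [m.group for m in metas]
    predictions: dict[int, list[str]] = {k: [] for k in ks}
    n_feat, n_sph = [], []
    for left_out in range(len(derived)):
        spheres = []
        for g in groups:
            members = [p for p in by_group[g] if p.id != ids[left_out]]
            sol = group_solution(members, group=g)
            spheres.extend(semantic_sphere_set(sol, items).spheres)
        sset = SphereSet(spheres=spheres)
        X = _cohort_feature_matrix(derived, sset, n_voxels=n_voxels)
        train = np.delete(np.arange(len(derived)), left_out)
        y_train = np.array([true[i] for i in train])
        n_feat.append(X.shape[1])
        n_sph.append(len(sset))
        for k in ks:
            sel = select_discriminative_features(X[train], y_train, k=k)
            model = gnb_train(X[train][:, sel], y_train,
                              variance_mode=variance_mode)
            scores = gnb_scores(model, X[left_out, sel])
            predictions[k].append(str(model.classes[int(np.argmax(scores))]))
    return GroupClassificationResult(participant_ids=ids, true_groups=true,
                                     predictions=predictions,
                                     n_features_available=n_feat,
                                     sphere_counts=n_sph)


# ---------------------------------------------------------------------------
# protocol 2: item decoding (within and across participants)
# ---------------------------------------------------------------------------

def within_participant_item_classification(d: ActivationDataset,
                                           spheres: SphereSet,
                                           n_voxels: int = 5,
                                           permute_labels_rng=None,
                                           ) -> tuple[float, np.ndarray]:
    """Decode the 16 items from a participant's own data.

    For each of the 15 ways to hold out 2 of the 6 presentation blocks: the
    classifier trains on per-block sphere features of the 4 training blocks
    (4 exemplars per item) and is tested on the mean of the 2 held-out
    blocks.  In-sphere stable-voxel choice uses training blocks only.
    ``permute_labels_rng`` (a Generator) shuffles training labels — the
    permutation null.  Returns (mean rank accuracy, (15, 16) per-fold table).
    """
    if d.data.shape[1] != N_BLOCKS:
        raise ValueError("within-participant decoding expects 6 blocks")
    membership = spheres.membership(d.grid)
    folds = list(itertools.combinations(range(N_BLOCKS), 2))
    acc = np.zeros((len(folds), N_ITEMS))
    for f, held in enumerate(folds):
        train_blocks = [b for b in range(N_BLOCKS) if b not in held]
        stab = voxel_stability(d, train_blocks)
        X_rows, y = [], []
        for b in train_blocks:
            feat = sphere_feature_rows(d.data[:, b, :], stab, membership,
                                       n_voxels=n_voxels)
            X_rows.append(feat.T)                       # (16, n_spheres)
            y.extend(range(N_ITEMS))
        X = np.vstack(X_rows)
        y = np.array(y)
        if permute_labels_rng is not None:
            y = permute_labels_rng.permutation(y)
        test_profile = d.data[:, held, :].mean(axis=1)
        T = sphere_feature_rows(test_profile, stab, membership,
                                n_voxels=n_voxels).T    # (16, n_spheres)
        model = gnb_train(X, y, variance_mode="pooled")
        scores = gnb_scores(model, T)                   # (16, 16)
        for i in range(N_ITEMS):
            acc[f, i] = rank_accuracy(scores[i], i)
    return float(acc.mean()), acc


def across_participant_item_classification(derived: list[ParticipantDerived],
                                           spheres: SphereSet,
                                           n_voxels: int = 5,
                                           ) -> np.ndarray:
    """Decode items in each participant from the rest of their group.

    Exemplars are block-averaged 24-sphere feature vectors (one per item per
    participant); classification is leave-one-participant-out with pooled
    variance.  Returns the per-left-out-participant mean rank accuracies.
    """
    if len(derived) < 3:
        raise ValueError("across-participant decoding needs at least 3 participants")
    grid = derived[0].dataset.grid
    membership = spheres.membership(grid)
    feats = [sphere_feature_rows(p.profile, p.stability, membership,
                                 n_voxels=n_voxels).T   # (16, n_spheres)
             for p in derived]
    out = np.zeros(len(derived))
    for left in range(len(derived)):
        X = np.vstack([feats[j] for j in range(len(derived)) if j != left])
        y = np.tile(np.arange(N_ITEMS), len(derived) - 1)
        model = gnb_train(X, y, variance_mode="pooled")
        scores = gnb_scores(model, feats[left])
        out[left] = np.mean([rank_accuracy(scores[i], i) for i in range(N_ITEMS)])
    return out
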