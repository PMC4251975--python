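"""Synthetic fMRI cohorts with a planted neurosemantic factor structure.

The generator emulates the study conditions of the social-interaction
paradigm: 17 autism-like + 17 control-like participants, 16 items (8 verbs x
agent/recipient role), 6 presentation blocks, ~15,000 voxels on a 4 mm grid.

Each participant's activation is a low-rank latent-factor signal plus iid
Gaussian noise:

    A(i, v, b) = sum_f a_f * kappa_f(v) * s_f(i)  +  idiosyncratic terms
                 + sigma * eps(i, v, b)

where ``s_f`` is a factor's 16-item score template, ``kappa_f`` a radial
Gaussian kernel around its (participant-jittered) region centers, and ``a_f``
a participant amplitude.  A posterior-midline "self" factor is strong in
control-like participants and near-absent (15% mean amplitude) in autism-like
participants, whose comparably ranked factor instead encodes the physicality
of the action (sensorimotor cortex); valence, accessibility and word-length
factors are shared.  Anatomical tract-density scalars and behavioral scores
of autism-like participants are planted to correlate with the residual
strength of their self factor (the stability of the planted posterior-midline
sphere), so the downstream brain-anatomy/behavior link analyses have a known
ground truth.

Template score values satisfy the published item orderings at the extremes;
the unconstrained middle entries are frozen calibration constants chosen to
make the five templates mutually near-orthogonal (max pairwise |r| = 0.10).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .io_core import (ActivationDataset, ItemSet, ParticipantMeta, VoxelGrid,
                      AUTISM, CONTROL, N_BLOCKS, N_ITEMS, canonical_item_set)
from .factor_pipeline import Sphere

__all__ = [
    "FACTOR_NAMES",
    "REGION_CENTERS",
    "PLANTED_SELF_SPHERE",
    "CohortConfig",
    "FactorTemplate",
    "ParticipantTruth",
    "GroundTruth",
    "make_item_set",
    "default_grid",
    "make_factor_templates",
    "simulate_participant",
    "simulate_cohort",
]

FACTOR_NAMES = ("self", "physicality", "valence", "accessibility", "word_length")

#: Stand-in region centers (mm, MNI-like): posterior cingulate/precuneus and
#: medial frontal for self; L pre/postcentral for physicality; caudate/putamen
#: for valence; middle cingulate, R angular and R superior medial frontal for
#: accessibility; occipital poles for word length.
REGION_CENTERS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "self": ((0.0, -60.0, 36.0), (6.0, 56.0, 24.0)),
    "physicality": ((-38.0, -12.0, 52.0), (-44.0, -24.0, 48.0)),
    "valence": ((-16.0, 8.0, 8.0), (16.0, 8.0, 8.0)),
    "accessibility": ((0.0, -18.0, 38.0), (48.0, -60.0, 36.0), (6.0, 56.0, 24.0)),
    "word_length": ((-12.0, -96.0, 2.0), (12.0, -96.0, 2.0)),
}

#: Main posterior-midline location of the self factor; the self-rudiment
#: readout of an autism-like participant is computed inside this sphere.
PLANTED_SELF_SPHERE = Sphere(center_mm=np.array([0.0, -60.0, 36.0]),
                             radius_mm=8.0, factor="self", source_group=CONTROL)

# Frozen raw template scores, canonical item order (verb-major, agent first).
# Extremes encode the published orderings; middles are calibration constants.
_RAW_SCORES: dict[str, list[float]] = {
    # compliment      insult        adore          hate        hug
    # kick            encourage     humiliate      (agent, recipient) each
    "self": [1.0, -1.348, 1.3, 1.2, -1.224, -1.459, 2.0, 1.4,
             0.951, 1.0, -2.0, -1.7, 1.0, -1.479, -1.5, 1.8],
    "physicality": [0.5, -0.74, -1.8, -1.7, -1.4, -1.4, -1.6, -1.5,
                    0.153, 1.6, 2.0, 1.9, 1.5, -1.282, -1.369, 0.5],
    "valence": [1.7, 1.6, -0.1, -0.207, 1.9, 1.8, -1.8, -1.7,
                1.5, 1.344, -1.488, -1.5, 1.086, 0.173, -1.9, -2.0],
    "accessibility": [2.0, 1.8, -1.9, -1.8, -2.0, -1.7, 1.382, 1.089,
                      1.9, 1.7, -0.746, -0.148, -1.312, 1.267, 1.127, -1.125],
}


def make_item_set() -> ItemSet:
    """The 16 social-interaction items in canonical order."""
    return canonical_item_set()


@dataclass(frozen=True)
class FactorTemplate:
    """A latent factor: name, zero-mean unit-sd 16-item score vector, region
    centers with a common kernel width, and the groups it is present in."""

    name: str
    scores: np.ndarray
    centers: np.ndarray          # (n_centers, 3) mm
    kernel_width_mm: float
    groups: frozenset[str]
    center_weights: np.ndarray | None = None

    def kernel(self, coords_mm: np.ndarray,
               centers: np.ndarray | None = None) -> np.ndarray:
        """Radial Gaussian loading field evaluated at ``coords_mm``."""
        ctrs = self.centers if centers is None else centers
        wts = (np.ones(len(ctrs)) if self.center_weights is None
               else np.asarray(self.center_weights, dtype=float))
        w2 = 2.0 * self.kernel_width_mm ** 2
        k = np.zeros(coords_mm.shape[0])
        for c, w in zip(ctrs, wts):
            d2 = ((coords_mm - c) ** 2).sum(axis=1)
            k += w * np.exp(-d2 / w2)
        return k


class TemplateOrderError(ValueError):
    """A score vector violates the published item-ordering constraints."""


def validate_templates(templates: dict[str, FactorTemplate],
                       item_set: ItemSet | None = None) -> None:
    """Check every ordering constraint the factor interpretations impose."""
    it = item_set or make_item_set()

    def require(cond, msg):
        if not cond:
            raise TemplateOrderError(msg)

    s = templates["self"].scores
    top = np.argsort(-s)
    require({int(top[0]), int(top[1])} ==
            {it.index("hate", "agent"), it.index("humiliate", "recipient")},
            "self top-2 must be hate/agent and humiliate/recipient")
    require({int(i) for i in top[2:5]} ==
            {it.index("hate", "recipient"), it.index("insult", "agent"),
             it.index("insult", "recipient")},
            "self ranks 3-5 must be hate/recipient, insult/agent, insult/recipient")
    require(int(top[-1]) == it.index("kick", "agent")
            and int(top[-2]) == it.index("kick", "recipient"),
            "self bottom-2 must be kick/recipient then kick/agent last")

    p = templates["physicality"].scores
    top = np.argsort(-p)
    require({int(i) for i in top[:4]} ==
            {it.index("kick", "agent"), it.index("kick", "recipient"),
             it.index("hug", "recipient"), it.index("encourage", "agent")},
            "physicality top-4 must be kick both roles, hug/recipient, encourage/agent")
    require({int(i) for i in top[-4:]} ==
            {it.index("hate", "agent"), it.index("hate", "recipient"),
             it.index("insult", "agent"), it.index("insult", "recipient")},
            "physicality bottom-4 must be hate and insult in both roles")

    v = templates["valence"].scores
    top = np.argsort(-v)
    require({int(i) for i in top[:4]} ==
            {it.index("adore", "agent"), it.index("adore", "recipient"),
             it.index("compliment", "agent"), it.index("compliment", "recipient")},
            "valence top-4 must be adore and compliment")
    require({int(i) for i in top[-4:]} ==
            {it.index("humiliate", "agent"), it.index("humiliate", "recipient"),
             it.index("hate", "agent"), it.index("hate", "recipient")},
            "valence bottom-4 must be humiliate and hate")

    a = templates["accessibility"].scores
    top = np.argsort(-a)
    require({int(i) for i in top[:4]} ==
            {it.index("compliment", "agent"), it.index("compliment", "recipient"),
             it.index("hug", "agent"), it.index("hug", "recipient")},
            "accessibility top-4 must be compliment and hug")
    require({int(i) for i in top[-4:]} ==
            {it.index("insult", "agent"), it.index("insult", "recipient"),
             it.index("adore", "agent"), it.index("adore", "recipient")},
            "accessibility bottom-4 must be insult and adore")

    w = templates["word_length"].scores
    letters = it.letter_count_vector()
    r = np.corrcoef(w, letters)[0, 1]
    require(r > 0.9999, "word_length scores must be proportional to letter counts")

    for t in templates.values():
        require(abs(t.scores.mean()) < 1e-9, f"{t.name} scores must be zero-mean")
        require(len(t.centers) >= 1, f"{t.name} needs at least one region center")


@dataclass
class CohortConfig:
    """Generator defaults define the emulated study conditions."""

    n_per_group: int = 17
    noise_sigma: float = 2.3          # iid noise sd per (item, block, voxel)
    amp_mean: float = 1.0             # amplitude of a present factor
    amp_sd: float = 0.2
    self_autism_mean: float = 0.15    # near-absent self rudiment in autism
    self_autism_sd: float = 0.12
    kernel_width_mm: float = 6.0
    center_jitter_mm: float = 2.0     # per-participant center displacement sd
    score_jitter: float = 0.5         # per-participant semantic idiosyncrasy sd
    n_idiosyncratic: int = 2          # participant-specific extra factors
    idio_amp_mean: float = 0.7
    idio_amp_sd: float = 0.2
    idio_width_mm: float = 8.0
    group_difference: bool = True     # False: autism-like generated as control-like
    # planted covariate correlations with the residual self-factor strength
    rho_tract_L: float = 0.50
    rho_tract_R: float = 0.17
    rho_benton: float = 0.72
    rho_wms_faces: float = 0.69
    rho_eyes: float = 0.78
    rho_ados: float = -0.21
    n_missing_benton: int = 1         # autism participants without a Benton score
    age_range: tuple[float, float] = (16.0, 38.0)
    fsiq_mean: float = 114.5
    fsiq_sd: float = 11.0
    fsiq_range: tuple[float, float] = (92.0, 139.0)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("age_range", "fsiq_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["age_range"] = list(d["age_range"])
        d["fsiq_range"] = list(d["fsiq_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def default_grid(spacing_mm: float = 4.0) -> VoxelGrid:
    """MNI-like 4 mm grid with an ellipsoidal brain mask of ~15,000 voxels.

    The mask is the union of the ellipsoid with 12 mm neighborhoods of every
    canonical region center, so all planted regions are fully in-brain.
    """
    shape = (int(round(160 / spacing_mm)), int(round(192 / spacing_mm)),
             int(round(160 / spacing_mm)))
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = (-78.0, -112.0, -60.0)
    ii, jj, kk = np.indices(shape)
    x = affine[0, 0] * ii + affine[0, 3]
    y = affine[1, 1] * jj + affine[1, 3]
    z = affine[2, 2] * kk + affine[2, 3]
    cx, cy, cz = 0.0, -18.0, 18.0
    ax, ay, az = 60.0, 78.0, 50.0
    mask = (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
            + ((z - cz) / az) ** 2) <= 1.0
    for ctrs in REGION_CENTERS.values():
        for c in ctrs:
            mask |= ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) <= 12.0 ** 2
    return VoxelGrid(affine=affine, mask=mask)


def make_factor_templates(config: CohortConfig | None = None,
                          raw_scores: dict[str, list[float]] | None = None,
                          ) -> dict[str, FactorTemplate]:
    """Build (and validate) the five factor templates.

    ``raw_scores`` may override the frozen defaults for the four semantic
    factors; vectors violating the ordering constraints raise
    :class:`TemplateOrderError`.
    """
    config = config or CohortConfig()
    item_set = make_item_set()
    raw = dict(_RAW_SCORES)
    if raw_scores:
        raw.update({k: list(v) for k, v in raw_scores.items()})
    raw["word_length"] = list(item_set.letter_count_vector())

    presence = {
        "self": frozenset({CONTROL}),
        "physicality": frozenset({AUTISM}),
        "valence": frozenset({AUTISM, CONTROL}),
        "accessibility": frozenset({AUTISM, CONTROL}),
        "word_length": frozenset({AUTISM, CONTROL}),
    }
    # the posterior cingulate/precuneus center is the self factor's main
    # location; its medial frontal satellite is weaker (and shared with the
    # accessibility network)
    center_weights = {"self": np.array([1.0, 0.6])}
    templates = {}
    for name in FACTOR_NAMES:
        s = np.asarray(raw[name], dtype=float)
        s = (s - s.mean()) / s.std(ddof=1)
        templates[name] = FactorTemplate(
            name=name, scores=s,
            centers=np.asarray(REGION_CENTERS[name], dtype=float),
            kernel_width_mm=config.kernel_width_mm,
            groups=presence[name],
            center_weights=center_weights.get(name))
    validate_templates(templates, item_set)
    return templates


@dataclass
class ParticipantTruth:
    """Everything planted for one participant."""

    id: str
    group: str
    amplitudes: dict[str, float]
    factor_scores: dict[str, np.ndarray]   # participant's jittered score vectors
    jittered_centers: dict[str, np.ndarray]
    idio_scores: np.ndarray          # (n_idio, 16)
    idio_centers: np.ndarray         # (n_idio, 3) mm
    idio_amps: np.ndarray            # (n_idio,)
    seed: int
    rudiment: float = np.nan         # realized planted-sphere self stability


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    templates: dict[str, FactorTemplate]
    config: CohortConfig
    participants: list[ParticipantTruth] = field(default_factory=list)
    seed: int = 0

    def template_matrix(self, group: str) -> tuple[np.ndarray, list[str]]:
        """(16, 4) score templates present in ``group``, with names."""
        names = [n for n in FACTOR_NAMES if group in self.templates[n].groups]
        return np.column_stack([self.templates[n].scores for n in names]), names


def _draw_participant_truth(pid: str, group: str, templates, config: CohortConfig,
                            grid: VoxelGrid, rng: np.random.Generator,
                            seed: int) -> ParticipantTruth:
    effective = group
    if not config.group_difference:
        effective = CONTROL
    amps: dict[str, float] = {}
    for name, t in templates.items():
        if name == "self":
            if effective == CONTROL:
                a = rng.normal(config.amp_mean, config.amp_sd)
            else:
                a = rng.normal(config.self_autism_mean, config.self_autism_sd)
            amps[name] = max(a, 0.0)
        elif name == "physicality":
            amps[name] = (max(rng.normal(config.amp_mean, config.amp_sd), 0.0)
                          if effective == AUTISM else 0.0)
        else:
            amps[name] = max(rng.normal(config.amp_mean, config.amp_sd), 0.0)
    jit = {name: t.centers + rng.normal(0.0, config.center_jitter_mm,
                                        size=t.centers.shape)
           for name, t in templates.items()}
    # each participant's semantic profile deviates from the group template
    fscores = {}
    for name, t in templates.items():
        s = t.scores + config.score_jitter * rng.standard_normal(N_ITEMS)
        fscores[name] = s - s.mean()
    n_idio = config.n_idiosyncratic
    idio_scores = rng.standard_normal((n_idio, N_ITEMS))
    idio_scores -= idio_scores.mean(axis=1, keepdims=True)
    sd = idio_scores.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    idio_scores = idio_scores / sd
    idio_centers = grid.coords_mm[rng.integers(0, grid.n_voxels, size=n_idio)]
    idio_amps = np.abs(rng.normal(config.idio_amp_mean, config.idio_amp_sd,
                                  size=n_idio))
    return ParticipantTruth(id=pid, group=group, amplitudes=amps,
                            factor_scores=fscores,
                            jittered_centers=jit, idio_scores=idio_scores,
                            idio_centers=idio_centers, idio_amps=idio_amps,
                            seed=seed)


def simulate_participant(truth: GroundTruth, ptruth: ParticipantTruth,
                         grid: VoxelGrid) -> ActivationDataset:
    """Deterministically synthesize one participant's activation tensor."""
    rng = np.random.default_rng(ptruth.seed)
    coords = grid.coords_mm
    signal = np.zeros((N_ITEMS, grid.n_voxels))
    for name, t in truth.templates.items():
        a = ptruth.amplitudes.get(name, 0.0)
        if a <= 0:
            continue
        kappa = t.kernel(coords, centers=ptruth.jittered_centers[name])
        scores = ptruth.factor_scores.get(name, t.scores)
        signal += a * np.outer(scores, kappa)
    w2 = 2.0 * truth.config.idio_width_mm ** 2
    for s, c, a in zip(ptruth.idio_scores, ptruth.idio_centers, ptruth.idio_amps):
        kappa = np.exp(-((coords - c) ** 2).sum(axis=1) / w2)
        signal += a * np.outer(s, kappa)
    sigma = truth.config.noise_sigma
    data = signal[:, None, :] + sigma * rng.standard_normal(
        (N_ITEMS, N_BLOCKS, grid.n_voxels))
    return ActivationDataset(participant_id=ptruth.id, data=data, grid=grid,
                             items=make_item_set())


def _planted_rudiment(d: ActivationDataset, sphere: Sphere,
                      n_voxels: int = 3) -> float:
    """Mean stability of the most stable in-sphere voxels (all 6 blocks)."""
    inside = np.flatnonzero(sphere.contains(d.grid.coords_mm))
    profiles = d.data[:, :, inside].transpose(1, 0, 2)
    from .voxel_selection import stability_from_blocks
    stab = stability_from_blocks(profiles)
    top = np.sort(stab)[-n_voxels:]
    return float(top.mean())


def _exact_corr_covariate(z: np.ndarray, rho: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Standardized covariate whose sample correlation with ``z`` is exactly
    ``rho`` (z must be standardized, ddof=1)."""
    n = len(z)
    e = rng.standard_normal(n)
    e = e - e.mean()
    e = e - (e @ z) / (z @ z) * z
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate residual when planting covariate")
    e = e / sd
    return rho * z + np.sqrt(1.0 - rho ** 2) * e


def simulate_cohort(config: CohortConfig | None = None,
                    seed: int = 0,
                    grid: VoxelGrid | None = None,
                    keep_datasets: bool = True,
                    groups: tuple[str, ...] = (AUTISM, CONTROL),
                    ) -> tuple[list[ActivationDataset] | None,
                               list[ParticipantMeta], GroundTruth]:
    """Generate a full cohort plus its ground truth.

    With ``keep_datasets=False`` the activation tensors are discarded after
    the per-participant self-rudiment is measured (memory-light mode for
    large-n covariate-recovery studies); metas and truth are still complete.
    ``groups`` restricts generation to one group (the covariate link study
    only involves the autism-like participants).
    """
    config = config or CohortConfig()
    grid = grid or default_grid()
    templates = make_factor_templates(config)
    truth = GroundTruth(templates=templates, config=config, seed=seed)

    root = np.random.SeedSequence(seed)
    n = config.n_per_group
    pids, group_of = [], []
    if AUTISM in groups:
        pids += [f"a{i + 1:03d}" for i in range(n)]
        group_of += [AUTISM] * n
    if CONTROL in groups:
        pids += [f"c{i + 1:03d}" for i in range(n)]
        group_of += [CONTROL] * n
    groups = group_of
    child_seeds = root.spawn(2 * n + 1)
    cov_rng = np.random.default_rng(child_seeds[-1])
    # seed children are positional (autism i -> child i, control i -> child
    # n+i) so a one-group run reproduces the same participants as a full run
    seed_of = {f"a{i + 1:03d}": child_seeds[i] for i in range(n)}
    seed_of.update({f"c{i + 1:03d}": child_seeds[n + i] for i in range(n)})

    datasets: list[ActivationDataset] | None = [] if keep_datasets else None
    ages, fsiqs, rudiments = [], [], []
    for pid, group in zip(pids, groups):
        ss = seed_of[pid]
        rng = np.random.default_rng(ss)
        pseed = int(ss.generate_state(1)[0] % (2 ** 31))
        pt = _draw_participant_truth(pid, group, templates, config, grid, rng, pseed)
        d = simulate_participant(truth, pt, grid)
        pt.rudiment = _planted_rudiment(d, PLANTED_SELF_SPHERE)
        truth.participants.append(pt)
        ages.append(rng.uniform(*config.age_range))
        fsiqs.append(float(np.clip(rng.normal(config.fsiq_mean, config.fsiq_sd),
                                   *config.fsiq_range)))
        rudiments.append(pt.rudiment)
        if keep_datasets:
            datasets.append(d)

    # covariates: planted against the autism group's realized self rudiments
    rhos = {"tract_density_L": config.rho_tract_L,
            "tract_density_R": config.rho_tract_R,
            "benton": config.rho_benton,
            "wms_faces": config.rho_wms_faces,
            "eyes": config.rho_eyes,
            "ados_social": config.rho_ados}
    scales = {"tract_density_L": (30.0, 5.0), "tract_density_R": (30.0, 5.0),
              "benton": (45.0, 4.0), "wms_faces": (35.0, 6.0),
              "eyes": (25.0, 4.0), "ados_social": (8.0, 2.0)}
    n_autism = sum(g == AUTISM for g in groups)
    cov_a: dict[str, np.ndarray] = {}
    if n_autism:
        rud_a = np.array(rudiments[:n_autism])
        z = rud_a - rud_a.mean()
        sd = z.std(ddof=1) if n_autism > 1 else 0.0
        z = z / sd if sd > 0 else np.zeros_like(z)
        if n_autism >= 4 and sd > 0:
            draw = lambda r: _exact_corr_covariate(z, r, cov_rng)
        else:
            # too few participants to orthogonalize; population construction
            draw = lambda r: (r * z + np.sqrt(1 - r ** 2)
                              * cov_rng.standard_normal(n_autism))
        cov_a = {k: scales[k][0] + scales[k][1] * draw(r)
                 for k, r in rhos.items()}
        missing = cov_rng.choice(n_autism,
                                 size=min(config.n_missing_benton, n_autism),
                                 replace=False)
        cov_a["benton"] = cov_a["benton"].copy()
        cov_a["benton"][missing] = np.nan

    metas = []
    for i, (pid, group) in enumerate(zip(pids, groups)):
        kw = dict(id=pid, group=group, age=ages[i], fsiq=fsiqs[i])
        if group == AUTISM:
            for k in rhos:
                kw[k] = float(cov_a[k][i])
        else:
            for k in ("tract_density_L", "tract_density_R"):
                mu, sc = scales[k]
                kw[k] = float(mu + sc * cov_rng.standard_normal())
        metas.append(ParticipantMeta(**kw))
    return datasets, metas, truth
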