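"""Statistical closure: decoding chance thresholds and brain-anatomy/behavior
links of the residual self factor.

The chance threshold for a *mean* rank accuracy treats each test
classification as assigning the true item a uniformly random rank among the
16; the exact null distribution of the mean follows by discrete convolution.
The self-rudiment measure of an autism-like participant is the mean stability
of the 3 most stable voxels inside the control group's main (posterior
cingulate/precuneus) self-factor sphere; it is correlated with cingulum tract
density (age-corrected) and with social-processing scores (age- and
FSIQ-corrected, Bonferroni m=4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ActivationDataset, ParticipantMeta, AUTISM
from .factor_pipeline import Sphere
from .voxel_selection import stability_from_blocks

__all__ = [
    "NullSpec",
    "chance_threshold",
    "exact_mean_rank_null",
    "self_rudiment",
    "partial_corr",
    "LinkResult",
    "LinkReport",
    "link_report",
    "compute_link_report",
]


@dataclass(frozen=True)
class NullSpec:
    """Null model for a mean of independent rank-accuracy observations."""

    n_classes: int = 16
    n_observations: int = 1
    alpha: float = 0.001

    def __post_init__(self):
        if self.n_classes < 2 or self.n_observations < 1:
            raise ValueError("need n_classes >= 2 and n_observations >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def exact_mean_rank_null(n_classes: int, n_observations: int) -> np.ndarray:
    """pmf of the integer sum S = sum of n iid uniform{0..n_classes-1} draws.

    Each observation contributes u = n_classes - rank, so the mean rank
    accuracy is S / ((n_classes - 1) * n).  Support: 0 .. n*(n_classes-1).
    """
    single = np.full(n_classes, 1.0 / n_classes)
    pmf = np.array([1.0])
    for _ in range(n_observations):
        pmf = np.convolve(pmf, single)
    return pmf


def chance_threshold(n_classes: int = 16,
                     n_observations: int = 1,
                     alpha: float = 0.001,
                     method: str = "exact",
                     n_draws: int = 1_000_000,
                     seed: int = 0) -> float:
    """Critical mean rank accuracy: the smallest achievable mean m* with
    P(mean >= m*) <= alpha under the uniform-rank null."""
    spec = NullSpec(n_classes=n_classes, n_observations=n_observations,
                    alpha=alpha)
    denom = (n_classes - 1) * n_observations
    if method == "exact":
        pmf = exact_mean_rank_null(n_classes, n_observations)
        tail = np.cumsum(pmf[::-1])[::-1]           # tail[k] = P(S >= k)
        ks = np.flatnonzero(tail <= alpha + 1e-15)
        if ks.size == 0:
            raise ValueError("alpha unattainable even at the maximal mean")
        return float(ks[0]) / denom
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        sums = rng.integers(0, n_classes,
                            size=(n_draws, n_observations)).sum(axis=1)
        counts = np.bincount(sums, minlength=denom + 1)
        tail = np.cumsum(counts[::-1])[::-1] / n_draws
        ks = np.flatnonzero(tail <= alpha)
        if ks.size == 0:
            raise ValueError("alpha unattainable in the Monte-Carlo sample")
        return float(ks[0]) / denom
    raise ValueError(f"unknown method {method!r}")


def self_rudiment(d: ActivationDataset,
                  self_sphere: Sphere,
                  n_voxels: int = 3,
                  blocks=None) -> float:
    """Mean stability of the ``n_voxels`` most stable voxels inside the
    control group's main self-factor sphere (all 6 blocks by default)."""
    inside = np.flatnonzero(self_sphere.contains(d.grid.coords_mm))
    if inside.size == 0:
        raise ValueError("the self sphere contains no in-mask voxel")
    blocks = list(blocks) if blocks is not None else list(range(d.data.shape[1]))
    profiles = d.data[:, blocks, :][:, :, inside].transpose(1, 0, 2)
    stab = stability_from_blocks(profiles)
    top = np.sort(stab)[-min(n_voxels, stab.size):]
    return float(top.mean())


def partial_corr(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Rows with any missing value are excluded casewise.  Both variables are
    residualized on the covariates plus an intercept by least squares; the
    correlation of the residuals is tested against a t distribution with
    n - 2 - k degrees of freedom (two-sided).  With no covariates this is
    exactly the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = (np.empty((len(x), 0)) if covariates is None
         else np.atleast_2d(np.asarray(covariates, dtype=float)))
    if C.shape[0] != len(x):
        C = C.T
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    x, y, C = x[keep], y[keep], C[keep]
    n, k = len(x), C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n), C])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if (rx.std() <= 1e-10 * max(1.0, x.std())
            or ry.std() <= 1e-10 * max(1.0, y.std())):
        raise ValueError("zero residual variance: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = min(max(r, -0.9999999999), 0.9999999999)
    t = r_ * np.sqrt(df / (1.0 - r_ ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


@dataclass
class LinkResult:
    variable: str
    covariates: tuple[str, ...]
    r: float
    p: float
    p_adjusted: float
    n: int
    reliable: bool


@dataclass
class LinkReport:
    results: list[LinkResult] = field(default_factory=list)

    def __getitem__(self, variable: str) -> LinkResult:
        for res in self.results:
            if res.variable == variable:
                return res
        raise KeyError(variable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])


_TRACT_VARS = ("tract_density_L", "tract_density_R")
_BEHAVIOR_VARS = ("benton", "wms_faces", "eyes", "ados_social")


def link_report(rudiments: np.ndarray,
                metas: list[ParticipantMeta],
                bonferroni_m: int = 4,
                min_n: int = 6) -> LinkReport:
    """Correlate the self-rudiment with anatomy and behavior.

    ``rudiments`` is aligned with ``metas`` (autism-like participants only).
    Tract densities are corrected for age; the four behavioral scores for age
    and FSIQ, with Bonferroni adjustment over those four comparisons.
    Missing scores drop participants per-association; associations with fewer
    than ``min_n`` usable participants are flagged unreliable.
    """
    if any(m.group != AUTISM for m in metas):
        raise ValueError("link analyses are defined for the autism-like group")
    rud = np.asarray(rudiments, dtype=float)
    age = np.array([m.age for m in metas])
    fsiq = np.array([m.fsiq for m in metas])
    report = LinkReport()

    def run(var: str, covs: dict[str, np.ndarray], m_corr: int):
        vals = np.array([getattr(meta, var) for meta in metas], dtype=float)
        C = np.column_stack(list(covs.values()))
        usable = int((np.isfinite(vals) & np.isfinite(rud)
                      & np.isfinite(C).all(axis=1)).sum())
        r, p = partial_corr(vals, rud, C)
        report.results.append(LinkResult(
            variable=var, covariates=tuple(covs), r=r, p=p,
            p_adjusted=min(1.0, m_corr * p), n=usable,
            reliable=usable >= min_n))

    for var in _TRACT_VARS:
        run(var, {"age": age}, m_corr=1)
    for var in _BEHAVIOR_VARS:
        run(var, {"age": age, "fsiq": fsiq}, m_corr=bonferroni_m)
    return report


def compute_link_report(datasets: list[ActivationDataset],
                        metas: list[ParticipantMeta],
                        self_sphere: Sphere,
                        n_voxels: int = 3) -> tuple[LinkReport, np.ndarray]:
    """Self-rudiments plus the link report for the autism-like members."""
    pairs = [(d, m) for d, m in zip(datasets, metas) if m.group == AUTISM]
    rud = np.array([self_rudiment(d, self_sphere, n_voxels=n_voxels)
                    for d, _ in pairs])
    return link_report(rud, [m for _, m in pairs]), rud
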