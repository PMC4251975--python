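# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. All empirical statements below are computed by
the test suite (`tests/`) or the analysis drivers (`analysis/`).

## Data model

A participant's data form a tensor A(i, b, v) over 16 items (8 verbs x
agent/recipient role, in a fixed canonical order: the verbs in listing order
*compliment, insult, adore, hate, hug, kick, encourage, humiliate*, agent
before recipient), 6 presentation blocks, and the in-mask voxels of a common
grid. Values are percent-signal-change-like and unitless. On disk a dataset
is a 4D NIfTI-1 volume (canonical volume order item-major/block-minor,
out-of-mask voxels stored as NaN, so the brain mask is recoverable as the
all-finite voxel set) plus a TSV sidecar naming each volume; loading honors
the sidecar, not the physical volume order. Missing metadata (e.g. an absent
Benton score) is carried as NaN and never imputed.

## Synthetic cohort generator

The generator emulates the study conditions: 17 + 17 participants, a 40 x 48
x 40 grid at 4 mm with an ellipsoidal brain mask of 15,666 voxels (the union
of the ellipsoid with 12 mm neighborhoods of the region centers, so every
planted region is fully in-brain).

Activation is a low-rank latent-factor signal plus iid Gaussian noise:

    A(i, v, b) = sum_f a_{p,f} * kappa_f(v) * s_{p,f}(i)
                 + sum_j a_{p,j} * kappa_j(v) * s_{p,j}(i)     (idiosyncratic)
                 + sigma * eps(i, v, b)

* **Score templates** s_f: zero-mean, unit-sd 16-vectors for five factors —
  self, physicality, valence, accessibility, word length. The published item
  orderings pin the extremes (e.g. self: *hate*/agent and
  *humiliate*/recipient highest, *kick* in both roles lowest; physicality:
  *kick* both roles, *hug*/recipient, *encourage*/agent highest and
  *hate*/*insult* lowest; valence: *adore*/*compliment* vs
  *humiliate*/*hate*; accessibility: *compliment*/*hug* vs *insult*/*adore*;
  word length proportional to verb letter counts). The unconstrained middle
  entries are free parameters; they were chosen once by numerical search
  minimizing pairwise template correlation subject to the ordering
  constraints and semantically plausible signs, then frozen (max pairwise
  |r| = 0.10). A validation routine rejects any override that violates an
  ordering.
* **Loading fields** kappa_f: sums of radial Gaussian kernels (width 6 mm)
  around canonical MNI-like centers — self: posterior cingulate/precuneus
  (0, −60, 36) weighted 1.0 (the factor's main location) plus medial frontal
  (6, 56, 24) weighted 0.6; physicality: L precentral/postcentral; valence:
  bilateral caudate/putamen; accessibility: middle cingulate, R angular,
  R superior medial frontal; word length: both occipital poles. Centers are
  jittered per participant (sd 2 mm).
* **Group structure**: the self template is present only in the control-like
  group (amplitude ~ N(1.0, 0.2) truncated at 0); autism-like participants
  receive a *rudimentary* self amplitude (truncated N(0.15, 0.12), i.e. 15%
  of the control mean — near-absent but variable, which the link analyses
  require) and a physicality factor (N(1.0, 0.2)) that controls lack
  entirely. Valence, accessibility and word length are shared.
* **Heterogeneity**: each participant's effective score vector is the
  template plus zero-mean Gaussian jitter (sd 0.5, re-centered), modelling
  individual semantic variation; two idiosyncratic factors per participant
  (random scores, random compact 8 mm loading fields, amplitude ~ |N(0.7,
  0.2)|) give first-level solutions content beyond the group factors.
* **Noise**: sigma = 2.3 per (item, block, voxel). The noise scale and the
  score-jitter sd were calibrated once against the headline study behavior
  (decoding accuracies off the ceiling, four-factor variance explained in
  the low/mid 40s, stable-voxel stability ~0.24 in controls) and then
  frozen.
* **Covariates**: tract densities (both hemispheres) and four behavioral
  scores are planted for autism-like participants against the *realized*
  self-rudiment (the stability readout of the planted posterior-midline
  sphere computed from that participant's generated data), using a
  construction whose sample correlation equals the planted rho exactly
  (0.50, 0.17, 0.72, 0.69, 0.78, −0.21). Planting against the realized
  readout rather than the latent amplitude is deliberate: the rudiment is a
  saturating, noisy function of the amplitude at near-absent signal levels,
  and the scientific claim being emulated concerns the *residual measurable
  strength* of the self factor. One autism-like participant's Benton score
  is blanked, mirroring the study's missing datum. Ages are uniform in
  16–38; FSIQ ~ N(114.5, 11) clipped to 92–139; controls get independent
  tract densities and no behavioral scores.

Everything is deterministic given the seed (per-participant child seeds from
a `SeedSequence`), and a one-group run reproduces byte-identical
participants of the corresponding full run.

**What the generator does not emulate**: hemodynamic time courses, motion
and physiological artifacts, spatially correlated noise, anatomical
variability beyond center jitter, and any nonlinearity between factors.
Passing recovery tests therefore demonstrates the correctness and internal
consistency of the pipeline under its own model class, not performance on
real scanner data.

## Stable-voxel selection

stability(v) = mean over the 15 block pairs of the Pearson correlation of
the two 16-item profiles. A zero-variance block profile contributes
correlation 0 to its pairs (degenerate voxels must not poison selection).
Selection takes the top-27 voxels by stability in each of 5 disjoint region
masks (ties by voxel index), totalling 135. The default masks are built by
assigning every voxel within 16 mm of a canonical region center to its
nearest center's factor region; the identity of the study's five areas is
not public, so the masks are fully configurable.

## Two-level factor analysis

Both levels share one extraction: Pearson correlation matrix of the
variables, principal-component extraction of the leading factors, varimax
rotation, and regression-method scores standardized to unit column sd.

* With 16 observations and 135 (level 1) or n·7 (level 2) variables the
  correlation matrix is rank-deficient by construction; maximum-likelihood
  factor analysis is ill-posed here, which is why extraction is
  principal-component based. The regression-score weights use a
  pseudo-inverse that keeps only the numerically meaningful part of the
  spectrum (relative cutoff 1e−6).
* Varimax is Kaiser's pairwise-rotation algorithm with row (communality)
  normalization and the closed-form per-pair angle; unlike gradient/SVD
  schemes it does not stall on symmetric saddle points (a perfectly mixed
  45-degree configuration is rotated to simple structure). Column signs are
  fixed so each factor's largest-|loading| entry is positive. Convergence:
  relative criterion improvement below 1e−10, cap 2000 sweeps.
* Factor counts are fixed at 7 (level 1) and 4 (level 2); `kaiser_count`
  (eigenvalues strictly greater than 1) is provided to reproduce the modal
  selection procedure that motivated 7.
* A voxel (level 1) or a first-level factor (level 2) is *linked* to the
  factor with its maximal |loading| when that exceeds 0.4 (configurable).
  A group factor's traced voxels are pooled over its assigned first-level
  factors across participants, with multiplicity; loading products supply
  signs and tie-break weights.
* Traced voxels are clustered by 26-connectivity connected components;
  components rank by pooled member count (ties by summed |loading|); the
  top 6 become spheres (center = member centroid, radius = max
  centroid-to-member distance + half a voxel). Variance explained per group
  factor is the sum of squared rotated loadings over the number of
  variables.
* Recovered factors are identified against reference score templates by the
  injective assignment maximizing total |score correlation| (exhaustive over
  permutations). For protocol-internal use, the word-length factor is
  identified without ground truth as the factor most correlated with the
  verb letter counts.

## Decoding protocols

Sphere features: per sphere, the item profiles of its 5 most stable in-mask
voxels (stability from the protocol's stated block subset) are averaged and
z-scored across the 16 items with the sample (ddof = 1) sd. GNB uses
per-feature Gaussians with a variance floor of 1e−6; pooled variance is the
default for 16-class decoding (at most 4 exemplars per class makes per-class
variances unstable), and the 2-class group protocol also defaults to pooled
after it proved equally accurate and more stable across feature counts.
Rank accuracy uses average ranks for ties.

* **Group membership** (leave-one-participant-out, 34 folds): each fold
  refits both groups' full two-level analyses on the 33 training
  participants only; each group contributes its 3 semantic factors
  (word-length excluded) with 6 spheres each; features are computed for all
  34 participants (the protocol withholds the test participant's *label*,
  not their data, mirroring the study's procedure); the top k = 115 features
  by absolute training-group-mean difference feed the classifier. Per-fold
  derivations that depend only on a single participant's own data
  (stability, voxel selection, first-level FA) are computed once and reused
  across folds — this is an exact optimization, not an approximation,
  because those quantities are identical in every fold that includes the
  participant.
* **Within-participant items**: all 15 ways of holding out 2 of 6 blocks;
  training exemplars are per-block feature vectors of the 4 training blocks
  (stability from training blocks only); the test exemplar is the mean of
  the held-out 2.
* **Across-participant items**: leave-one-participant-out within a group;
  exemplars are block-averaged feature vectors (16 per training
  participant). Per-block training exemplars were considered and rejected
  in favor of block means, which match the described training-set size.

## Statistical closure

* The null for a mean of n independent rank accuracies treats each
  observation as (16 − r)/15 with r uniform on 1..16; the integer sum
  distribution follows by discrete convolution, and the threshold is the
  smallest achievable mean m* with P(mean >= m*) <= alpha. For the
  within-participant protocol (n = 240 = 15 folds x 16 items,
  alpha = .001) this gives 0.5614 -> 0.56 at 2 dp. A Monte-Carlo method
  (1e6 draws) cross-checks the convolution.
* The self-rudiment of a participant is the mean stability (all 6 blocks)
  of the 3 most stable voxels inside the control group's main self-factor
  sphere. When that sphere comes from a factor analysis its outer radius is
  noise-driven, so the link analysis probes the sphere's 8 mm core; top-3
  order statistics over a wide region would bury the faint autism-like
  signal under selection noise.
* "Corrected for" is implemented as partial correlation by
  residualization: both variables are regressed on the covariates plus an
  intercept, the residuals correlated, and the two-sided p-value taken from
  a t distribution with n − 2 − k degrees of freedom. Missing values drop
  participants casewise per association. Tract-density associations use age
  as the covariate; the four behavioral associations use age and FSIQ and
  are Bonferroni-corrected with m = 4. Associations with fewer than 6
  usable participants are flagged unreliable.

## Problem sizes and determinism

The default study scale (17 + 17 participants, 15,666 voxels, 4 mm grid) is
used throughout the tests and the acceptance script; the covariate-recovery
study runs 500 autism-like participants in a memory-light streaming mode,
and replicate studies (null cohorts, sign-recovery) use 20–100 seeds. All
randomness flows from explicit integer seeds.

## Known limitations

* The five selection areas and the exact quota rule of the original
  procedure are not public; the defaults here (factor-region neighborhoods,
  equal quota 27) preserve the stated structure but are a reconstruction.
* Extraction/rotation/score choices (PCA + varimax + regression scores,
  threshold 0.4) are declared package conventions, not inferred fact.
* Sphere geometry (centroid + max-distance radius) is one reasonable
  reading of "clusters characterized as spheres".
* The generator's effect sizes are calibrated, not estimated from data;
  absolute accuracies on synthetic cohorts exceed those reported on real
  data at matched protocol settings, and only the qualitative pattern
  (group separation, above-chance decoding, factor substitution) should be
  compared.
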