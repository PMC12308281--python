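# Methods

## The model

`strokelink` analyses two participant-aligned data blocks: X (participants ×
brain features: Fisher-z FC edges, or SDC edge proportions) and Y
(participants × behavioural measures).  Both blocks are column-standardized
(mean 0, sample SD with ddof = 1), so the cross-block matrix
`R = Yzᵀ Xz/(n−1)` is a correlation matrix.  A covariance mode (centering
only) exists behind `scale_mode="covariance"` but is not the default: the
analysis correlates the blocks, and correlation implies unit-variance
columns.  The SVD `R = V diag(s) Uᵀ` gives paired saliences; components are
sign-fixed so the largest-magnitude entry of each behavioural salience is
positive (the SVD leaves each component's sign free; the convention makes
fits deterministic across platforms).  Explained covariance is `s_k²/Σs_j²`.
Composite scores are plain projections of standardized data (not normalized
by singular values), matching the loading definition: loadings are Pearson
correlations between original variables and composite scores.

Standardization policy for projection: a whole new cohort is standardized
with its own column statistics (`standardize="self"`, the cross-cohort
default, since feature scales can differ between acquisitions); single
held-out rows — which have no statistics — use the training-fold statistics
(`standardize="fit"`), which is what the LOOCV routines do.  Sample-SD
(ddof = 1) standardization is used throughout; population SD would only
rescale `R` uniformly and leave saliences, explained covariance and all
p-values unchanged.

## Resampling inference

**Permutation test.**  Y rows are shuffled against a fixed X (the standard
behavioural-PLS null; shuffling X instead is equivalent in distribution),
the model is refitted, and the observed `s_k` is compared with the null
distribution of the k-th sorted singular value.  P-values use the +1
Monte-Carlo smoothing `(1 + #{null ≥ obs})/(1 + n_perm)`; q-values are
Benjamini–Hochberg across components.  The null distribution of `s_1` is
positive and not centered at zero — only exceedance counting is ever
asserted.  A variant that Procrustes-aligns each permuted solution to the
observed one before reading off singular values is available
(`align=True`) but is not the default: aligning null components to a
reference that is itself noise spreads the null covariance across
components and, measured empirically, inflates the LC1 null rejection rate
from ~0.04 to 0.57–1.0 at desk-scale dimensions.  Alignment is therefore
reserved for the bootstrap, where sign/order coherence of the resampled
components is exactly what is needed.

**Bootstrap.**  Participants are resampled with replacement (draws with
fewer than 3 distinct participants are redrawn and counted); each refit is
Procrustes-rotated onto the observed solution — rotation estimated from the
behavioural block, the smaller and better-conditioned one, with an X-block
option — and loadings are recomputed *within* the bootstrap sample from the
aligned saliences.  FC-edge loadings are averaged within and between
hemisphere-qualified network blocks *before* dispersion summaries, limiting
multiple comparisons to block pairs; an edge-level mode exists for small
schemes.  z = observed (block) loading / bootstrap SD (SD floored at 1e-12),
two-sided normal p, BH-FDR across blocks per component.

**Procrustes rotation.**  For reference saliences `V_ref` and target
`V_t` with singular values `s_t`:  `N = V_refᵀ V_t`, SVD `N = P diag(d) Qᵀ`,
rotation `= Q Pᵀ`; aligned saliences are `(V_t diag(s_t)) · rotation` with
aligned singular values read off as column norms before renormalization.

## Ridge prediction

Structural features predict LC1 composite scores under leave-one-out
cross-validation.  Per outer fold: all-zero training columns are dropped,
features are standardized with training-fold statistics (prevents leakage),
α is selected from the 16 integer powers of two in 2⁻¹⁰…2⁵ by minimizing
the training fold's exact leave-one-out MSE — computed through the
hat-matrix identity `e_loo = (y − ŷ)/(1 − h)`, which for penalized least
squares with an unpenalized intercept equals explicit refits to machine
precision (the test suite checks ≤ 1e-8) — ties go to the smaller α, and
the refitted model predicts the held-out participant.  The solver is the
SVD closed form; a converged gradient descent reaches the same optimum
(tested to 1e-6), so the closed form is used for speed and exactness.
Pooled predictions are scored by Pearson r, MAE, and R² about the mean of
the *measured* targets — the convention under which out-of-sample R² can be
negative (uninformative features genuinely predict worse than the mean).

## Mediation

Three-variable path model on per-participant composite scores with OLS
paths (a: x→m; c: total; b, c′ from y ~ x + m), indirect effect ab, and the
exact OLS identity ab = c − c′ asserted on every fit.  Inference is by
participant-level bootstrap with the bias-corrected (BC, not BCa — no
acceleration term) percentile rule: z₀ = Φ⁻¹(fraction of bootstrap ab below
the estimate), CI at the Φ(2z₀ ± z_{α/2}) quantiles.  Coefficients are
unstandardized by default with a standardized mode (all three variables
z-scored) alongside; the proportion mediated ab/c is scale-free either way.
Both mediation orientations are always reported
(`model1_fc_mediator`, `model2_sdc_mediator`); results are statistical
associations, not causal effects, since mediator and outcome are measured
simultaneously.

## The synthetic cohort generator

The generator emulates the study conditions the analysis assumes, with full
ground truth:

- **Geometry.**  A voxel grid (default 24×12×12) split into hemispheres
  along x.  Parcels are mirror-symmetric voxel blocks confined to the top
  `cortex_fraction` (default 0.5) of the z-axis — a cortical sheet — with
  balanced network assignments (default 13 networks/hemisphere, one parcel
  each).  Streamlines connect every parcel pair (default 5 per pair),
  diving through the free deep space like association/commissural tracts
  (`route_depth`), with Gaussian vertex wobble (sd 0.5 voxels) and vertex
  spacing ≤ 1 voxel.  The cortex/white-matter separation is what lets a
  small deep lesion disconnect many tracts while damaging little grey
  matter — the anatomical reason SDC out-predicts focal damage.
- **Lesions.**  One spherical unilateral lesion per participant, radius
  uniform in (2, 4) voxels, center uniform within one hemisphere.  Severity
  is the fraction of atlas streamlines the lesion intersects.
- **Latent chain.**  t = standardized severity + Gaussian noise
  (sd 0.5), restandardized.  FC edges: `X = baseline + g_x·t·uᵀ + σ_x·E`;
  behaviour: `Y = 10 + g_y·t·vᵀ + σ_y·E`, with σ_x = σ_y = 1.  Gains are
  calibrated as `g = σ·sqrt(ρ/(1−ρ))` so each block's planted composite
  correlates √ρ with t and the population correlation between the two
  planted composites equals `latent_effect` ρ (default 0.7); the
  Monte-Carlo calibration test verifies this.  Because FC and behaviour
  share only t, conditioning on the FC composite attenuates the
  SDC→behaviour association — the planted mediation structure.
- **Planted saliences.**  The FC salience u is negative on interhemispheric
  edges between sensory-like networks (first half of the network list) and
  positive on intrahemispheric edges involving higher-order networks,
  echoing the decreased-interhemispheric / increased-intrahemispheric
  stroke pattern.  The behaviour salience v sweeps from strong to near-zero
  within domains with one contrarian (sign-flipped) measure, so it has
  genuine variance around its mean — a near-constant profile would make
  Pearson-correlation recovery measure only noise.
- **Missingness** is MCAR at rate 0.05 (every measure kept observable at
  least once).  Real cohort missingness is not MCAR; mean imputation is the
  behaviour under test, not the missingness mechanism.
- **Determinism.**  One seed per cohort; sub-streams (atlas, lesions,
  noise, missingness) at fixed offsets.  A replication cohort reuses the
  ground truth (saliences, scheme, atlas) with a fresh participant seed.

Default cohort size is 81 participants with 41 measures in 5 domains.  The
default parcellation is 13 parcels/13 networks per hemisphere (26 parcels,
325 edges): the generator is parcellation-size-agnostic and a full
333-parcel scheme (55 278 edges) adds nothing statistically at n = 81 while
multiplying runtime by orders of magnitude.

What the generator does **not** emulate: haemodynamics and autocorrelated
BOLD noise, vascular-territory lesion shapes, spatially correlated FC noise,
bilateral lesions, longitudinal recovery.  Passing tests therefore show the
*machinery* is correct and calibrated under the assumed generative model,
not that real cohorts satisfy those assumptions.

## Study sizes used by the simulation tests

The parameter-recovery and cross-cohort studies run at n = 100 with a
planted effect of 0.7 on a reduced cohort: 4 parcels/4 networks per
hemisphere (28 edges) and 20 measures in 5 domains.  These sizes come from a
design-time power analysis of rank-1 cross-correlation identifiability: at
n = 100 and ρ = 0.7 the per-block aggregate signal is capped at
√(ρ/(1−ρ)) ≈ 1.53 regardless of feature count, so salience recovery decays
with feature-space size, and with the full 41-measure panel the
behaviour-salience recovery plateaus below 0.9 for any edge count.  The
null-coverage study for the mediation CI uses n = 30: with a product of two
null coefficients the bootstrap interval becomes degenerately conservative
as n grows (coverage → 1), and the small-sample regime is where bias
correction is consequential.  Null calibration of the permutation test uses
200 runs × 200 permutations at n = 50.

## Numerical choices

- Fisher z: r clipped to ±(1 − 1e-7) before atanh, keeping duplicated
  series finite.
- Streamline–lesion intersection: a streamline is disrupted iff any vertex,
  rounded to its voxel, is lesioned (vertex spacing ≤ 1 voxel, no sub-voxel
  segment clipping) — discrete, order-invariant, and exactly testable.
- Parcel pairs with no atlas streamlines get SDC 0, keeping the edge space
  dense.
- Group-level FC assembly: per-edge mean imputation over participants for
  edges missing due to per-participant parcel exclusions; edges missing in
  every participant are dropped with an index map (union exclusion across
  81 heterogeneous lesions would gut the feature space).
- Exclusion threshold is *strictly* greater than 50% damage.
- `top_fraction` keeps ⌈fraction·m⌉ entries; ties at the cut go to the
  lower index so the mask size is exact.
- LOOCV-of-PLSC fold models are Procrustes-aligned to the full-sample fit
  before projecting the held-out row, making component sign/order coherent
  across folds; the pooled (not per-fold-averaged) correlation is the
  statistic.
- Split-half uses ⌈n/2⌉/⌊n/2⌋ disjoint random halves.
- Zero-variance columns inside resampling draws are centered and left at
  zero rather than raising, so bootstrap loops never die on degenerate
  draws; fit-time standardization of user data still raises, naming the
  column.

## Known limitations

- Block-level bootstrap inference has no pooling advantage when every
  network holds a single parcel (each block pair is one edge); at the
  default n = 81 and 325 edges, individual edge loadings are rarely
  significant even though LC1 itself is — visible in the seed-1 analysis
  run.  Larger parcel-per-network counts give the block averaging its
  intended power.
- In-sample composite-score correlations are optimistic (LC1 r ≈ 0.93 at
  n = 81, p = 325 for a planted 0.7); the LOOCV and replication projections
  (≈ 0.56) are the honest generalization estimates.
- The cross-stage projection requires identical feature columns; there is
  deliberately no silent column intersection — the caller subsets
  explicitly and a mismatch raises with the offending names.
- The aligned-permutation variant exists for completeness but should not be
  used for inference (see above).
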