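# Methods

`crossfc` re-implements, as a tested pipeline over synthetic data, the
resting-state functional-connectivity analysis of a two-treatment,
two-period crossover fMRI design: each subject is scanned at rest before
dosing (RS0) and about an hour after dosing (RS1) under both an active
drug ("verum") and placebo, and the question is whether the drug changes
connectivity from RS0 to RS1 more than placebo does (the time-by-drug
interaction).

## Synthetic cohorts (`crossfc.simdata`)

Real participant data for this kind of trial are not redistributable, so
the package ships a generator that plants known connectivity structure and
every downstream stage is validated by recovering it.

A session's BOLD signal is a sum of four parts:

1. **Hub communities.** Each hub region shares one latent signal; voxels
   participate with heterogeneous weight (amplitude 2.0 times a uniform
   0.25–1.75 factor drawn per voxel and session, against unit voxel
   noise).  Strong members correlate far above the 0.6 edge threshold
   while weak-member pairs fall below it even after band-pass denoising,
   so edge counts vary across voxels and subjects the way real hub
   strength does — a homogeneous community would connect every voxel to
   every other in every session, making the across-subject hub maps
   degenerate (zero variance) at full session length.
2. **Seed–target coupling.** Seed voxels carry `a*u`; target voxels carry
   `a*(r*u + sqrt(1-r^2)*v)` with `v` independent of `u`, so the latent
   seed–target correlation is exactly `r` (negative by default,
   `coupling_r = -0.5`, emulating amygdala–prefrontal anticorrelation).
   Under placebo `r` is constant; under verum it shifts by
   `interaction_delta` at RS1, so the subject-level difference of
   differences equals `interaction_delta` on the latent scale.  A
   per-subject jitter (`subject_coupling_sd = 0.08`) adds between-subject
   heterogeneity that cancels in the interaction contrast.
3. **Tissue nuisance.** White-matter and CSF slabs carry their own common
   signals (amplitude 1.0), which CompCor must remove.
4. **Artifacts.** Volumes are spiked at `spike_rate = 0.02` with a
   transient translation in the motion file (1.5 mm default; configurable
   above 3 mm to trigger subject exclusion) plus a global intensity
   offset in the same volume.  Spikes are never planted in adjacent
   volumes: detection works on frame-to-frame differences, and the second
   of two identical adjacent offsets is indistinguishable from a stable
   displaced head.

All latent signals are unit-variance Gaussian processes band-limited to
0.01–0.1 Hz (white noise through a zero-phase 4th-order Butterworth), so
they pass the preprocessing band-pass undistorted and recovery tests probe
the analysis rather than the generator.  Defaults mirror the emulated
trial: TR 2 s, 355 volumes, 3 mm voxels, 35 subjects split 18/17 between
the verum-first and placebo-first sequences, ages uniform on [31, 59].
The spatial grid is a compact 12x12x12 block with a WM slab, a CSF slab
and a gray-matter body — a geometric caricature, not an anatomical atlas.
Every random stream is spawned from `rng_seed` plus the (subject, drug,
session) coordinates, so identical configurations reproduce cohorts bit
for bit regardless of generation order.

What the generator does **not** emulate: hemodynamic response functions,
scanner drift and physiological quasi-periodicity, anatomical geometry,
spatially varying smoothness, and distance-dependent noise correlations.
Passing recovery tests therefore demonstrate correctness of the analysis
chain on signals with the planted covariance structure, not performance on
real scanner data.

## Preprocessing (`crossfc.preprocess`)

Per session, on already-aligned data:

1. discard the first 5 volumes (T1 equilibration);
2. build a 19-column nuisance design: the top 5 principal-component time
   courses of the pooled WM+CSF voxels (each voxel linearly detrended and
   standardized first; components extracted via the time-by-time Gram
   matrix), the 12-parameter motion expansion (6 rigid-body parameters plus
   first backward differences, first difference row zero), a linear trend,
   and an intercept;
3. flag bad volumes: composite framewise displacement above 0.9 mm
   (sum of absolute translation increments plus rotation increments
   converted to arc length at a 65 mm head radius) or global-mean
   intensity change above 5 standard deviations;
4. exclude a subject/condition outright when flagged volumes exceed 30% of
   the time course or any translation parameter exceeds 3 mm — both strict
   inequalities, so 30.0% and 3.0 mm exactly are kept;
5. regress the nuisance design plus one indicator column per flagged
   volume out of every voxel in a single least-squares fit
   (scrubbing-by-regression keeps temporal spacing uniform for the filter;
   deletion is available via `scrub_mode="delete"`), then band-pass the
   residuals to 0.01–0.1 Hz with a zero-phase 2nd-order Butterworth.
   The global signal is never regressed.

Derived 3D maps (never raw series) are smoothed with a Gaussian kernel of
8 mm FWHM (`sigma = FWHM / (2*sqrt(2*ln 2))` per axis, in voxel units).

## Connectivity maps

**gFCD** (`crossfc.gfcd`): for gray-matter voxel *i*, `K[i]` counts voxels
*j != i* in the mask with Pearson correlation strictly greater than the
threshold (0.6 default; 0.4 and 0.5 as robustness settings).  Negative
correlations never count; zero-variance voxels get `K = 0` with a warning.
`K` is normalized by its gray-matter mean `K0`, making `mean(K/K0) = 1` an
exact identity.  Correlations are computed blockwise (unit-norm rows, one
block-by-all matrix product at a time) so memory is
`O(block_size x V)`; the result is independent of the block size and is
tested for exact equality against a naive `numpy.corrcoef` double loop.

**Seed FC** (`crossfc.seedfc`): the seed time course is the unweighted
mean over seed voxels; each brain voxel's Pearson correlation with it is
Fisher-transformed, `z = atanh(r)`, with `|r|` clamped at `1 - 1e-7` so
seed self-voxels stay finite.  Seed voxels are retained in the map and
flagged in the provenance sidecar.  Under independence the across-voxel
sd of `z` is approximately `1/sqrt(T-3)`.

## Group inference (`crossfc.stats`)

*Validation maps.* One-sample t-tests of the stacked subject maps from
each subject's first-period pre-dose session: gFCD against 1 (one-sided
"greater", voxel-level FWE by max-statistic sign-flipping permutation) and
seed-z against 0 (two-sided, Benjamini–Hochberg FDR), both at 0.05.

*Interaction.* The within-subject ANOVA with covariates is operationalized
as the per-subject difference of differences
`Delta_i = (verum_RS1 - verum_RS0) - (placebo_RS1 - placebo_RS0)`
regressed voxel-wise on an intercept plus mean-centered age and a centered
sequence indicator; the intercept t (df = n - 3) is the covariate-adjusted
interaction statistic.  Without covariates and with balanced sequences
this is algebraically the classical 2x2 repeated-measures interaction
(F = t^2), which the tests verify against a hand-computed closed form and
`statsmodels` `AnovaRM` on a 6-subject fixture.  Main effects of time and
drug use the analogous cell-average contrasts.

*Cluster-level FWE.* Voxels with |t| above the two-sided Student quantile
for the height threshold (p < 0.001) form 18-connected components of each
sign (6/26 configurable).  The null distribution of the maximum cluster
size — over both signs — is built by sign-flipping each subject's
contrast map and recomputing the full t-map and labeling per flip;
`p_fwe = (1 + #{perm max >= k}) / (1 + n_perm)`.  Sign-flipping replaces
random-field-theory cluster correction deliberately: it is exact under the
symmetry of the null contrast distribution, needs no smoothness
estimation, and its calibration is testable at desk scale.  An exploratory
uncorrected mode (p < 0.005, extent > 10) exists behind an explicit flag.

*Post hoc.* Paired t-tests (df = n - 1) on cluster-mean smoothed z values:
verum vs placebo at each session, RS1 vs RS0 within each drug.  Clusters
are selected by the interaction test itself, so these are descriptive
follow-ups.  Zero-variance paired differences return t = +-inf with p at
the subnormal floor rather than crashing.

## Numerical choices and edge cases

- Zero-variance detection uses a relative tolerance
  (`norm <= 1e-10 * (max|x| + 1)`), because a constant series whose mean
  is not exactly representable does not center to exactly zero.
- Edge threshold ties (r exactly 0.6) are non-edges (strict inequality).
- The scrub indicator columns make the regression residual exactly zero at
  flagged volumes, so cleaned values are provably insensitive to arbitrary
  corruption of the raw data there.
- `cluster_fwe` requires at least 100 permutations; empty suprathreshold
  sets return an empty cluster list, not an error.
- Voxel coordinates are 0-based internally; user-facing tables report mm
  via the affine.

## Monte-Carlo validation and problem sizes

The test suite and the acceptance script validate the chain at reduced
dimensions chosen so the full battery runs on one CPU in minutes:

- **Null calibration**: 200 replicate null cohorts (20 subjects, 12^3
  grid, 120 volumes, `interaction_delta = 0`), each run through the full
  generate -> preprocess -> seed-FC -> interaction -> 500-permutation
  cluster-FWE chain.  The familywise rejection rate at alpha = 0.05 must
  fall in [0.02, 0.09], and pooled interaction t values (at spatially
  spaced voxels — smoothing correlates neighbors, which would invalidate
  the KS sampling assumption) must match Student t(17).
- **Recovery**: 50 single-session replicates for hub ranking and for the
  sign of the planted negative coupling; 25 replicate cohorts for
  interaction detection at the study's 35 subjects.
- **Effect-size calibration**: the planted coupling shift for the recovery
  experiment is sized to a per-voxel Cohen's d of 1 on the subject-level
  interaction contrast.  A white-noise formula underestimates the contrast
  noise, because band-limiting to 0.01–0.1 Hz leaves roughly a third of
  the nominal degrees of freedom; the attenuation of latent couplings and
  the contrast sd are therefore estimated once from a deterministic
  24-subject pilot simulation under the null
  (`experiments._pilot_interaction_scaling`).
- At 20 subjects, a per-voxel d of 1 against the t(17) quantile for
  p < 0.001 has only ~0.6–0.7 voxel-level power, so reliable (>=80%)
  cluster detection at that effect size needs the study-sized cohort; the
  recovery experiment uses n = 35 accordingly, while the null calibration
  keeps n = 20 (calibration does not depend on power).

## Known limitations

- The difference-score formulation of the covariate-adjusted ANOVA is the
  standard equivalent for a complete 2x2 within-subject design; it does
  not generalize to missing cells (subjects with incomplete cells are
  dropped, with a warning).
- The ART-style "intermediate" scrub thresholds (0.9 mm composite motion,
  z = 5 intensity) are the documented toolbox defaults, not values printed
  in any trial report; both are config-overridable.
- The seed region in real analyses is a cytoarchitectonic probability map
  thresholded at 80%; the package takes any binary seed mask as input and
  ships only the synthetic toy seed.
- Permutation p-values are granular at `1/(n_perm + 1)`; with 500
  permutations the smallest attainable p is ~0.002.
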