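# Methods

## Synthetic experiment design

The generator reproduces the list structure of the study: a pool of 512
synthetic word tokens (w0001…w0512) in 8 disjoint lists of 64, half
labeled concrete and half abstract. Words carry no lexical properties —
only list membership matters downstream, so frequency/concreteness
matching is not modeled. The counterbalance id selects which half of the
lists is studied; over a two-id cycle every list is studied exactly once.
The study list holds 256 words, half assigned one presentation and half
three. Each of 8 test runs contains 16 once-studied, 16 thrice-studied and
32 new words plus 4 null events, in random order, with a 500 ms fixation,
3000 ms word, and an inter-trial interval drawn uniformly from
2000–6000 ms. Four runs are incentivize-old and four incentivize-new, in
random order. Word-to-run allocation is uniform at random within the cell
counts (the allocation rule beyond randomization is not otherwise
constrained, so this is the natural choice).

## Behavioral simulation

Two parameterizations generate responses:

* **Rate mode (default).** Each of the six (run type × item type) cells
  has a probability of an "old" response; the defaults are the group
  means of the reference behavioral table (hits 0.74/0.93 and false
  alarms 0.29 under incentivize-old; 0.63/0.86 and 0.17 under
  incentivize-new), so the criterion shift is built into the cell
  probabilities. Per-subject probabilities are drawn from a
  mean-preserving Beta distribution with concentration 32, giving
  between-subject rate SDs of ~0.04–0.08 and cohort SEMs near the
  reported ~0.02–0.03. A Beta draw (rather than logit-normal jitter) keeps
  the cohort mean exactly at the cell probability.
* **SDT mode.** Equal-variance Gaussian model: old-item strength
  ~ N(d′, 1), new-item strength ~ N(0, 1), respond "old" when strength
  exceeds λ = d′_ref/2 + c, with d′_ref the run type's mean old-item d′,
  so c = 0 is the unbiased point — the convention under which the d′ and
  c estimators are consistent. Subject-level d′ and c are Normal around
  the condition means (SDs 0.30 and 0.15).

RTs are lognormal with σ = 0.30 and condition-specific locations set so
the means match the reported correct-RT cell means. Null events require a
key press but no memory decision and are excluded from the response table.

## Behavioral statistics

Hit and correct-rejection rates are per-cell proportions of correct
responses; RT summaries use correct trials only. Hit rates are pooled
over 1x and 3x items by trial-weighted averaging (identical to the plain
mean at the design's equal counts). d′ = z(H) − z(F); the criterion
defaults to the standard location measure c = −½[z(H) + z(F)], which
yields negative (liberal) values when both rates are high — the sign
convention matching the reported values; the literal opposite-sign form
is available via a flag. Extreme rates are replaced by 1/(2N) and
1 − 1/(2N) (count-aware, conventional) before the probit transform.
Group d′/c are means of per-subject values, not statistics of group-mean
rates: the reported group values (d′ = 1.62 vs 1.53 from group-mean
rates) are only consistent with per-subject averaging.

The paired t test reports Cohen's dz = t/√n. The TOST procedure tests
H0: |dz| ≥ Δ with t_lower = (dz + Δ)√n and t_upper = (dz − Δ)√n on n − 1
df; equivalence requires both one-sided tests to reject at α = 0.05. The
large-effect bound is taken as dz = 0.80 (Cohen's convention; only "a
large effect-size result" is stated). The two-way within-subject ANOVA
uses the standard sums-of-squares partition, each effect tested against
its own subject-interaction error term, with partial
η² = SS_effect/(SS_effect + SS_error); no sphericity correction (the
3-level factor makes ε corrections a minor refinement out of scope).

## GLM stage

The hemodynamic response is a canonical double-gamma kernel (gamma-density
peak at ~5 s, undershoot at ~16 s with 1/6 amplitude), sampled at the 2 s
TR and normalized to unit peak; it substitutes for an unspecified
block-function basis, being standard, closed-form and testable. Condition
regressors are word-duration boxcars (fractional scan occupancy at the
edges) convolved with the kernel; nulls are modeled as a nuisance
regressor; an intercept and (by default) a linear drift complete the
design. Betas are per-voxel OLS, averaged per condition across runs.
No temporal filtering, autocorrelation modeling, or motion correction —
preprocessing is out of scope, and the simulated noise is white.

## Image simulation and planted ground truth

Condition images live on a desk-scale 10×10×10 grid of 2 mm isotropic
voxels (identity-plus-offset affine, RAS+); larger grids are supported.
The generative model is

X[s, c, ·] = grand mean + Σₗ aₗ vₗ[c] uₗ + subject offset + coupling + ε,

with unit-norm task profiles vₗ and spatial maps uₗ (Gaussian blobs, so
BSR maps have realistic local maxima), voxelwise subject offsets shared
across conditions (removed exactly by mean-centering — the structure task
PLS assumes), and i.i.d. Gaussian noise. Seed couplings add a latent
factor z[s, c] to a seed cube and a distal coupled cube, scaled so the
cross-subject voxel-to-voxel correlation equals the requested r given the
non-shared variance; z is centered across subjects within condition, so
coupling induces correlation without shifting condition means. The
default model plants a repetition pattern (amplitude 2.5), a weaker
targetness pattern (amplitude 1.75), and a target-only seed coupling
(r = 0.8) — amplitudes chosen so that, at 14 subjects and 1000 voxels,
the task LVs are detectable by permutation (p < 0.05) while the maps stay
visibly noisy, mirroring a study that found marginally significant LVs.

What the generator does **not** emulate: spatial noise correlation
(smoothness), physiological noise spectra, anatomical structure, or
registration error. Passing tests therefore demonstrate estimator
correctness and calibration under the assumed model, not performance on
real fMRI data.

## Task PLS

Rows of the stacked data matrix are (condition, subject) pairs in
condition-block order; columns are voxels in C order of the grid. The
decomposition acts on the k × V matrix of condition means centered about
the grand mean (the standard mean-centered task-PLS variant; a
full-matrix mode could be exposed but condition means are the toolbox
default and the balanced design makes unweighted means exact). No
voxelwise variance normalization is applied — the decomposition is of
covariance, not correlation. At most k − 1 LVs are nonzero. SVD signs are
fixed by flipping each LV so its largest-|salience| voxel is positive
(ties by lowest voxel index). Brain scores are X·u per subject-condition
image.

Condition groupings: *repetition* contrasts 3x vs 1x hits, pooled over
run types by default (both pooled and unpooled entries are supported;
pooled is the default since the contrast of interest is two-level);
*targetness* contrasts targets (1x hits under incentivize-old + CRs under
incentivize-new) against non-targets (1x hits under incentivize-new +
CRs under incentivize-old), using 1x items only, whose memory status is
most criterion-sensitive.

## Seed PLS

Seed activity is the mean of the condition beta over the seed voxel and
its adjacent voxels (27-voxel cube, clipped at volume edges). A
time-series path exists for end-to-end demos: the mean over an 8-TR
trial-locked window's peak-adjacent timepoints, defined as TRs 2–4
(4–8 s post-onset, bracketing the canonical response peak; configurable).
Betas are the primary input — they are what the rest of the pipeline
produces. Seed values are Pearson-correlated with every voxel across
subjects within condition (zero-variance voxels give r = 0 with a
warning); correlations are not Fisher-z transformed before the SVD
(toolbox convention; a transform flag would change only monotonically).

## Resampling inference

**Permutation.** Condition labels are shuffled within subject (subjects
are the exchangeable blocks; unrestricted row permutation is available).
Singular values of the permuted decomposition are compared rank-wise to
the observed ones; p = (r + 1)/(N + 1), a valid p under exchangeability
that avoids p = 0, with minimum 1/(N + 1). A whole-spectrum comparison
("any") is available. Note an implication for seed PLS: within-subject
label permutation only re-attributes connectivity across conditions, so
it tests the *condition-specificity* of seed coupling, not its
existence — a condition-general correlation component (e.g., the seed's
self-correlation block) is never significant under this null, by design.

**Bootstrap.** Subjects are resampled with replacement (default 100
replicates; single-subject resamples are redrawn and logged) and the full
analysis — including the correlation maps for seed PLS, since
correlations are subject-level statistics — is recomputed. Replicates are
aligned to the original decomposition by orthogonal Procrustes rotation
of the task-salience space (absorbing sign and axis indeterminacy; for
k = 2 this reduces to a sign flip). The BSR is the original
singular-value-weighted salience divided by the bootstrap SE; it behaves
approximately like a z score and is thresholded at |BSR| > 3
(≈ p < 0.001). Zero-SE voxels receive a ±inf sentinel, count as reliable,
and are logged. No multiplicity correction across voxels is applied: the
pattern is estimated in a single analytic step.

**Peaks.** Local maxima of |BSR| (3×3×3 neighborhood) above threshold are
accepted greedily by decreasing |BSR| with a 10 mm exclusion radius
(reporting rules such as cluster extent are not otherwise specified;
these defaults are documented choices), ties broken by lexicographic
voxel index; coordinates are reported in mm through the grid affine.

## Numerical choices and problem sizes

Singular values below a 1e−12 relative tolerance are dropped. The
acceptance and property suites run at desk scale — grids of 10³ voxels or
smaller, 100–500 permutations, 60–100 bootstrap replicates, 200-replicate
type-I-error studies — sizes at which every check is exact or its Monte
Carlo error is well inside the asserted tolerance. The matrix-level
signal-to-noise ratio used in recovery tests is the planted amplitude
divided by the expected Frobenius norm of the noise in the centered
condition-mean matrix (for k = 2, n subjects, V voxels and per-voxel
noise σ: σ√(V/n)); per-voxel definitions would not be comparable across
grid sizes, since centered-mean noise accumulates over voxels.

## Known limitations

* The generator's noise is white in space and time; all calibration
  statements are conditional on that.
* The rate-mode simulator draws each cell's subject probability
  independently, so cross-condition subject correlations (and hence the
  between-condition d′ effect-size structure) are weaker than in real
  cohorts; the SDT mode models them only through shared run-type
  criteria.
* Permutation and bootstrap defaults (500/100) follow standard PLS
  practice; at these counts the smallest attainable p is ~0.002 and BSR
  SEs carry ~7% Monte Carlo noise.
* Anatomical labeling, smoothing, registration and post-hoc tests are
  out of scope.
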