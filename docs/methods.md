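# Methods

## The analysis chain

`patsim` implements a multivariate pattern-similarity analysis of
recognition memory in two age groups. The chain is: single-trial beta
estimation → cross-run similarity measures → searchlight maps → cluster-mass
permutation inference → interindividual and trial-wise models. Each stage
is a pure function of its inputs, the configuration, and one integer seed
(split into per-subject/per-stage streams by stable hashing, so results are
identical under any evaluation order or parallelism).

### Single-trial GLM (least-squares-separate)

Each trial is estimated by its own OLS model: a trial-specific regressor, a
pooled regressor for all other trials of the run (both stimulus
categories), six motion regressors, and an intercept. Trial regressors are
1.2-s boxcars convolved with the canonical double-gamma HRF (response gamma
peaking at 6 s, undershoot at 16 s, unit dispersions, peak:undershoot ratio
6, 32-s support, peak-normalized). Convolution is computed on a 0.1-s grid
and sampled at scan times because the 1.2-s events are sub-TR. No temporal
filtering, prewhitening, or drift model beyond the intercept is applied;
all-zero motion columns (motion-free simulations) are dropped to keep the
design full rank. Rank-deficient designs flag the trial and set it to
missing.

A known property of the pooled-nuisance design, made explicit here: exact
recovery of planted amplitudes from noise-free data holds only when the
non-target trials of a voxel share one amplitude (then the nuisance series
lies in the span of the pooled column). With heterogeneous per-trial
amplitudes and the paradigm's dense 0.5–8-s ITIs, cross-trial leakage caps
the beta-recovery correlation near 0.82 regardless of noise level; with
separated 4–12-s events the correlation exceeds 0.9 at unit noise. The
estimation benchmarks use these two regimes respectively.

### Similarity measures

All measures are means of Fisher z-transformed Pearson correlations between
trial beta patterns over a voxel set, with pairs restricted to different
runs (same-run pairs share slow haemodynamic noise and never enter any
measure). Correlation magnitudes are capped at 1 − 1e−7 before atanh, which
diverges at |r| = 1 on noise-free fixtures. Per-stimulus means are computed
first and then averaged across stimuli; undefined pairs (zero-variance
patterns) are dropped with the pair count decremented, never zero-filled.

* category specificity = within-category (same category, different item) −
  between-category similarity, per phase;
* category-level reinstatement = within-category − between-category
  encoding→recognition similarity, computed against each encoding run and
  averaged; recognition partners include old and new items by default
  (old-only is a flag);
* item-level reinstatement = within-item − within-category reinstatement.

Trial-wise variants use the same pairing rules per anchor trial; the
subject-level recognition specificity equals the mean of its trial-wise
values exactly, which the tests assert algebraically.

### Searchlight

Spheres contain every integer offset within the Euclidean radius (boundary
inclusive; 257 offsets at 8 mm on the 2-mm grid, 33 at 4 mm, 925 at 12 mm).
Spheres are intersected with the mask without padding; centres with fewer
than `min_voxels` (default 10) in-mask voxels are undefined, because
correlations over tiny voxel sets are unstable. Only isotropic grids are
supported; anisotropic affines raise. A batched implementation (gather →
centre → einsum over pair correlations) computes the standard measures and
is asserted to match per-centre direct metric calls to 1e−12.

### Cluster-mass permutation inference

Voxel-wise statistics: one-sample t against zero (whole-group), pooled-
variance two-sample t (age contrast), or the t of an OLS slope
(brain–behavior). Two-sided threshold at `voxel_alpha` = 0.005; connected
components under 26-connectivity (configurable 6/18), positive and negative
voxels labelled separately; cluster mass = Σt. The null is the
per-permutation maximum |mass| across both signs — the max-statistic
convention, conservative and standard for family-wise control.
p = (1 + #{null ≥ mass}) / (1 + n_perm) avoids zero p-values; clusters are
reported at p < 0.05 with ≥ 10 voxels. When `n_perm` reaches the number of
distinct permutations the test enumerates them exactly. Permutation
matrices are drawn up front from the seed, so results are independent of
chunking or worker count. Age and behavior tests restrict their search
space to the union of significant whole-group clusters; the behavioral
covariate (category-matched Pr) is shuffled rather than the maps,
preserving the maps' spatial covariance.

### Interindividual models

Pr = hit rate − false-alarm rate per category and overall; subjects with
Pr < 0 are flagged for exclusion. The 2 (age) × 2 (category) mixed ANOVA is
delegated to `pingouin.mixed_anova` and checked against a hand sum-of-
squares decomposition. Brain–behavior relations use Pearson correlations
(all subjects, and within each age group) with the two-sample Fisher z-test
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). Nested OLS comparisons
use the partial F = ((RSS₁−RSS₂)/Δdf)/(RSS₂/df₂); for a single added
regressor this equals the squared coefficient t, asserted numerically.

### Trial-wise logistic mixed models

`LogisticGLMM` fits logit P(hit) = x'β + z'bᵢ, bᵢ ~ N(0, Σ), by maximizing
the Laplace-approximate marginal likelihood: per-subject joint modes by
damped Newton (vectorized across subjects), Σ parameterized by its
log-Cholesky factor, outer optimization by L-BFGS-B (log-SDs bounded in
[−6, 4]). Wald SEs invert the observed information over β at the estimated
Σ — the convention of the standard mixed-model packages, cross-checked
against `lme4::glmer` on a fixture (coefficients agree to ~5e−4; SEs to a
few percent, reflecting package-level information conventions).
Non-convergence walks the ladder full → diagonal → intercept-only, recorded
on the results object; complete separation (detected by diverging pooled
estimates) falls back to Firth-penalized fixed-effects logistic regression,
flagged. Age is coded −0.5 (young) / +0.5 (old); response bias is the
subject's overall proportion of "old" responses; hippocampal-style ROI
activity is the trial-wise ROI mean z-scored within subject (zero variance
guarded to zeros with a warning). Continuous covariates enter unscaled.

## The synthetic study

The generator emulates the design the analyses assume: two identical
encoding runs presenting every "old" item once per run in alternating
category blocks (starting category counterbalanced across subjects), and a
two-run recognition test jointly presenting each old and new item once.
ITIs are uniform on 0.5–8 s; stimulus duration 1.2 s; TR 2 s.

Per trial, the voxel pattern is

    s_t·T_cat (category block) + g·T_item (item block) + noise,

with subject-specific templates T_cat ~ N(0, cat_signal_sd²),
T_item ~ N(0, item_signal_sd²) shared across runs and phases (the shared
item template *is* the reinstatement signal), group factor g = 1 (young) or
`dediff_factor_old` (old) — the planted dedifferentiation — and latent trial
distinctiveness s_t = g·max(0, N(1, 0.3)). Category and item templates live
in two disjoint 5³ blocks (one per category) so that each category's
specificity map has a spatially compact truth region; for searchlight maps
the truth region is that block dilated by the sphere radius, since a map
carries signal wherever the sphere overlaps the block.

Memory outcomes follow a logistic link: for old items
P("old") = σ(bias_group + u₀ + (slope + u₁)·s_t) with subject random
intercept (SD 0.5) and slope (SD 0.3); new items use the intercept alone.
Defaults chosen once to mirror the qualitative behavioral pattern of this
literature: bias_young = logit(0.26), bias_old = logit(0.42) (so the old
group shows elevated hit *and* false-alarm rates with similar Pr),
memory_slope = 1.0, cat_signal_sd = 1.0, item_signal_sd = 0.5,
noise_sd = 1.0, dediff_factor_old = 0.5. The logistic link between
distinctiveness and memory is an assumption of this test harness — it makes
the within-person effect recoverable by the GLMM — not a claim about the
generative process in real data.

What the generator does **not** emulate: spatial noise autocorrelation
(voxel noise is i.i.d. by default; smoothing is optional), physiological or
scanner artifacts, haemodynamic variability across regions, anatomical
structure (the "brain" is a box; ROI masks are user-supplied), and
non-logistic memory processes. Passing tests therefore demonstrate that the
estimators and tests recover what they are defined to recover under their
own assumptions — not that those assumptions hold in human data.

### Null-map emulation for calibration

Type-I calibration of the cluster test uses per-subject null maps generated
directly (Gaussian fields smoothed with σ = 2 voxels, matching the intrinsic
smoothness of searchlight maps, whose neighbouring spheres share most
voxels). Unsmoothed maps would make the ≥ 10-voxel reporting filter absorb
nearly all rejections and push the family-wise rate toward zero; smooth
maps exercise the test in the regime it is used in. Running the full
simulation + searchlight chain for hundreds of null datasets would measure
the same exchangeability property at orders of magnitude more cost.

## Problem sizes

Desk-scale defaults (12 subjects/group, 12 items/category, 20³ grid at
2 mm) keep a full pipeline run in minutes. The committed validation
conditions: type-I calibration on 500 null datasets (24 subjects, 20³
maps, 200 permutations); age-contrast recovery on 50 end-to-end runs (12³
grid, dediff 0.5, 8-mm searchlights, 200 permutations) scoring Dice overlap
between significant age clusters and dilated planted truth; memory-slope
recovery over 100 GLMM fits (24 subjects × 24 old trials, slope 1.0);
sign-flip p-uniformity over 1000 simulations at 199 permutations with a
permissive 0.3 voxel threshold (keeping the max-mass statistic effectively
continuous so its null p-values are comparable to uniform).

## Known limitations

* LSS leakage at dense ITIs (above) biases single-trial betas toward their
  neighbours; similarity measures inherit this as a small same-run
  correlation inflation, which the cross-run pairing rule removes from all
  reported measures.
* The Laplace approximation slightly biases variance components downward in
  small clusters of binary trials; fixed-effect CIs remain near-nominal at
  the committed sizes (checked by simulation).
* The max-statistic null with the minimum-size filter is conservative: the
  empirical family-wise rate sits near 0.04–0.06 at α = 0.05.
* Pr-based model comparisons use the largest significant cluster per
  measure by default; which cluster feeds which model is a configurable
  choice, not an identified quantity.
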