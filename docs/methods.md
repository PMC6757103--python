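# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package. Everything stated here is computed by the code
and exercised by the test suite; nothing refers to measurements the package
does not itself produce.

## Speckle tracking and Lagrangian strain

B-mode speckle is a quasi-stable interference texture that can be followed
frame to frame. A line ROI (default 15 mm) is placed longitudinally in the
muscle and sampled at every other pixel (`floor(length_px / 2) + 1` points;
83 points at the default 38 mm / 418 px resolution).

Point motion between consecutive frames is estimated with a pyramidal
Lucas–Kanade tracker written on numpy/scipy:

* Gaussian pyramid (default 3 levels, σ = 1, decimation ×2);
* per level, the 15×15 px template window around each point is fixed in the
  earlier frame, and the Gauss–Newton update
  `δ = −G⁻¹ b`, `G = Σ ∇I ∇Iᵀ`, `b = Σ (J − I) ∇I`
  is iterated (max 30 iterations, convergence 0.01 px) with bilinear
  interpolation for sub-pixel sampling;
* a point is invalid when its full-resolution window leaves the image or
  the minimum eigenvalue of `G` (per pixel) falls below 10⁻⁶ — a
  structureless window yields "invalid", never spurious motion. At coarse
  pyramid levels the same conditions merely skip refinement for that level,
  since border effects at decimated resolution say nothing about the
  full-resolution window.

Every landed point is re-tracked backwards; the distance between the
round-trip position and the original point is the forward–backward (FB)
error, and points with FB error > 2 px (the published threshold; pixels
assumed, as the source does not state units) are removed — permanently, so
correspondence with frame-0 positions is preserved. Raising the threshold
can only grow the surviving set (monotonicity, property-tested).

Tracking is sequential (frame k → k+1) with correspondence kept to frame 0,
matching the cumulative-sum description of the original software and
tolerating slow drift. The ROI endpoints are updated per frame by a
least-squares **1-D similarity** along the initial ROI axis: with initial
and current point projections x₀, x₁, the scale/shift pair minimising
`Σ(s·x₀ + u − x₁)²` is applied to the endpoint projections, and
`L_k = s · L_0`. A full 2-D affine fit would be degenerate for collinear
points; only longitudinal length matters for strain. Strain is Lagrangian,

    e_k = 100 · (L_k − L_0) / L_0  [%],

exactly 0 at frame 0, positive for elongation (the plotting convention puts
shortening below zero). Whether the original software derived length from
endpoint projection or summed point displacements is ambiguous in the
source description; endpoint length via the similarity fit is implemented.

On noise-free phantoms the tracked peak strain is within 0.1 pp of truth
(tests require ≤ 0.5 pp); with additive noise of sd 5 gray levels the
300-frame full-size phantom stays within 1 pp (typically ≤ 0.1 pp).

## Deformation areas

The deformation-vs-time curve is integrated by the composite trapezoidal
rule, `A = (Δt/2)(y₁ + 2y₂ + … + 2y_{n−1} + y_n)`, in units of %·s. Before
splitting lobes, a sample is inserted at every 0%-line crossing at its
linearly interpolated time, so each trapezoid lies in one lobe:
elongation area = sum of positive trapezoids, shortening area = magnitude
of the negative ones, total = their sum. Exact zeros are lobe boundaries
contributing no area — the unbiased, sign-flip-symmetric choice. Two
identities are property-tested: `total` equals the trapezoid area of |y|
with the same inserted crossings, and `elongation − shortening` equals the
signed area.

Trial aggregation takes the mean over the available trials of a
subject × muscle × %MVC cell (2 or 3; fewer raises an error naming the
cell). Two normalisations exist:

* **time**: each trial's areas divided by that trial's elapsed time
  (multivariate branch);
* **100% MVC**: each subject's values divided by their 100% MVC total area
  (per muscle by default, five-muscle-summed reference optional), making
  subjects with proportional profiles identical.

The analysis window is the full recorded trial; no sub-window is defined.

## Interaction features and preprocessing

Observations are subject × %MVC cells at the five submaximal levels
(10–80%; the 100% trials serve only as normalisation references). The ten
base columns (five muscles × elongation/shortening) are z-scored with the
sample sd, and all 45 unordered pairs are multiplied element-wise:

    i_ab = ((a − x̄_a)/s_a) ∘ ((b − x̄_b)/s_b).

Column names are canonical (`"TR_elo*SP_short"`, lexicographic pair order),
so layouts are reproducible. The base features are both time- and
100%-MVC-normalised: without the subject-size normalisation, the lognormal
between-subject spread of deformation magnitudes dominates every z-score
and the products become too heavy-tailed for any single-component model to
summarise.

Products of z-scores are signed, so a plain base-10 log is undefined on
them; preprocessing uses the odd, monotone transform
`L(x) = sign(x)·log10(1 + |x|)` (≈ log10 for large |x|), then column
centring and unit-variance scaling. This is a documented substitute for
the original (unspecified) signed-data handling, not a claim about it.

## PCA, OPLS, cross-validation, VIP

PCA (SVD-based, via scikit-learn) provides exploratory scores and
explained-variance fractions; orthonormality and the Eckart–Young
reconstruction identity are tested against an eigendecomposition oracle.

OPLS is fitted NIPALS-style for a single response: per orthogonal
component, `w ∝ Xᵀy`, `t = Xw`, `p = Xᵀt/tᵀt`,
`w_orth ∝ p − (wᵀp)w`, and the orthogonal variation `t_orth p_orthᵀ` is
deflated from X; the predictive component is then a 1-component PLS fit of
the deflated matrix. With zero orthogonal components the model **is**
1-component PLS (verified against scikit-learn's `PLSRegression` to
1e-10). Orthogonal scores are uncorrelated with the response to numerical
precision. The default of one orthogonal component follows the published
two-component (1 + 1) model; the count is an exposed parameter because no
general selection rule is given.

Cross-validation is leave-one-subject-out: all of one subject's
observations are held out together; the preprocessing statistics
(signed-log/centre/scale) and the model are refit on the remaining
subjects — the statistically safe reading, as refitting inside folds
prevents leakage. Reported are `Q²Y = 1 − PRESS/TSS` (TSS about the grand
mean), `RMSECV = √(PRESS/n)` in %MVC units, per-fold predictions and
held-out predictive/orthogonal scores (the cross-validated score plot).

VIP uses the predictive component's unit-norm weights:
`VIP_j = √(K·w_j²/Σw²)`, so mean(VIP²) = 1 exactly; VIP > 1 flags
importance. Loading classes ("High I" / "High II" / "Low") are emitted as
a thresholded partition — negative predictive loadings are Low, and
non-negative ones split at the top tertile of |loading| — a documented
reconstruction of a qualitative plot reading, not an original rule.

## Univariate statistics

Per-subject force–deformation fits: OLS polynomials of degree 1 and 2 on
the raw-data trial means across all six levels (including 100% MVC, an
assumption where the source is ambiguous), compared on
`adj R² = 1 − (1 − R²)(n − 1)/(n − p − 1)`; the larger adjusted R² wins,
ties to linear (parsimony). Strength categories use half-open intervals
covering [0, 1] without gaps: below-weak < 0.10, weak [0.10, 0.31),
moderate [0.31, 0.61), strong [0.61, 0.90], very strong (0.90, 1].

ICC: two-way ANOVA mean squares give ICC(2,1) (random trials, absolute
agreement, single measures — the test–retest convention, reported by
default) and ICC(3,1) (consistency); the exact variant used originally is
not reported, so both are computed. The 95% CI uses the McGraw–Wong
F/Satterthwaite construction; both estimates and intervals are
cross-checked against pingouin. Fleiss categories with half-open
boundaries: poor [0, 0.40), fair [0.40, 0.60), good [0.60, 0.75),
strong [0.75, 1]. Zero between-subject variance yields ICC 0 with a
warning.

One-way repeated-measures ANOVA: within-subject F from hand-computed sums
of squares; Mauchly's W on the orthonormal-contrast covariance with Box's
chi-square approximation (including the second-order term); when p < 0.05
both dfs are multiplied by the Greenhouse–Geisser
`ε = tr(S*)²/((k−1)tr(S*²))` of the double-centred condition covariance
(ε ∈ (1/(k−1), 1]). Pairwise follow-ups are Bonferroni-corrected paired
t-tests. With two conditions F equals the squared paired-t statistic
(tested), and sphericity holds trivially.

## Synthetic-data design

**Phantoms** emulate the acquisition geometry only: 486 × 418 px (rows ×
columns — which printed dimension is width is not stated; this assignment
and the 38 mm footprint → 0.0909 mm/px mapping are recorded assumptions),
50 frames/s, 6 s trials. Texture is Gaussian-blurred uniform noise (grain
1.5 px) — band-limited and trackable, with no claim to ultrasound physics
(no point-spread function, attenuation, or out-of-plane motion). A
horizontal band (the "muscle") is stretched by `(1 + e_k/100)` about its
centre via inverse-mapped bilinear resampling, so ground truth is
sub-pixel exact; strain profiles are ramp (3 s) – hold (2 s) – release,
matching the force task's timing. Additive Gaussian pixel noise is drawn
per frame. Everything is deterministic given the seed (bit-exact images).

**Cohorts** emulate the raw-data structure of a 20-subject study: 5
muscles × 6 levels (10–100% MVC) × 3 trials, one row per trial with
elongation/shortening/total areas and elapsed time (Normal(8.0, 0.65) s,
matching the recorded test-time scale). Components:

* *Planted force relationship*: per subject, mean total area vs %MVC is
  linear or quadratic through per-muscle anchors at 10% and 100% MVC set
  to the published group means (e.g. TR 19.2 → 63.6 %·s); default mix
  11 linear / 9 quadratic of 20.
* *Subject scaling*: lognormal factors (σ = 0.6, cv ≈ 0.65) reproduce the
  large between-subject spread of deformation magnitudes.
* *Muscle-specific activation profiles*: the elongation share of total
  area follows a logistic switch from 0.12 to 0.90 across the force range,
  with midpoints at 0.30/0.40 of the range for the deep semispinalis
  cervicis and multifidus and 0.50–0.65 for the superficial muscles —
  deep muscles deform maximally near 40% MVC, superficial near 60–80%.
  This one-sidedness is what makes interaction products monotone in %MVC:
  products of z-scores of *linear* co-monotone profiles are necessarily
  U-shaped (each z-profile crosses zero mid-range), so a monotone
  interaction plant requires lobe mass concentrated at one end.
* *Strategy variability* (`coactivation_sd`, default 0.15): per
  subject × level, one shared lognormal factor for all shortening lobes
  (spread fading with force) and one for all elongation lobes (spread
  growing), emulating occasion-to-occasion shifts between
  shortening-dominant and elongation-dominant behaviour.
* *Trial noise*: additive Gaussian (sd 10 %·s) per lobe, truncated at 0
  (areas are magnitudes), so `total = elongation + shortening` holds
  exactly by construction.

The **planted-signal recovery condition** used by the model-recovery tests
is `CohortSpec(subject_scale_sd=0.4, coactivation_sd=0.0,
trial_noise_sd=5.0)` — clean activation profiles with moderate noise. Under
it, OPLS leave-one-subject-out Q²Y exceeds 0.4 in ≥ 80% of seeded
replicates (typically ≈ 0.55). The default (noisier, strategy-variable)
cohort yields Q²Y ≈ 0.3–0.4 and R²Y ≈ 0.5.

What the generator does **not** emulate — and hence what passing tests do
not show about real recordings: speckle decorrelation, probe-pressure and
out-of-plane artifacts, the forward drift of the cervical spine at high
force, real trial-to-trial strategy switches *within* a level block (the
per-level strategy factor is shared across a level's trials, so the
simulated trial reliability, ICC ≈ 0.99 for the five-muscle sum, is higher
than real test–retest reliability), and the unknown true mm-per-pixel.

## Known limitations

* **Linear-plant selection under noise.** With six force levels, the
  probability that a quadratic fit beats a linear one on adjusted R² for
  truly linear data is scale-invariant (≈ P(F(1,3) > 3/4) ≈ 0.39
  regardless of noise sd), so noisy linear plants are re-identified only
  ~60% of the time under the larger-adjusted-R² rule; ties go to linear,
  so the noise-free case is always recovered, and quadratic plants are
  recovered ≥ 90% of the time. This is a property of the selection rule,
  not of the implementation.
* **One orthogonal component** is a convention, not an optimum; on the
  synthetic cohorts additional orthogonal components raise in-sample R²Y
  while degrading Q²Y (overfitting of fold-specific variation).
* The signed-log transform, the High I/II/Low partition rule, the ICC
  variant, the 100%-MVC normalisation of the feature branch and the
  486 × 418 row/column assignment are documented interpretations of an
  under-specified original analysis; each is isolated behind a flag or
  function where alternatives can be substituted.
* Degenerate inputs are defined, not accidental: structureless windows →
  invalid points; < 2 surviving points → tracking-lost error; zero-variance
  feature columns, missing cells, absent 100% MVC references → named
  errors; zero between-subject variance → ICC 0 with warning.

## Problem sizes

Default test and acceptance runs use the full-size phantom (486 × 418 ×
300 frames, 83 ROI points) for the headline tracking check and a reduced
phantom (220 × 160 × 150 frames) for unit tests; cohort analyses always
run at the full design (1800 rows, 100 observations × 45 features,
20 CV folds). Replicate counts are 20 permutations for the null check and
50 seeds for the recovery rates.
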