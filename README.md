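# specklestrain

Quantifying dorsal-neck-muscle deformation from B-mode ultrasound speckle
tracking, and relating it to isometric force.

Clinicians and movement scientists need non-invasive measures of neck-muscle
function. Ultrasound speckle patterns act as natural tissue markers: a short
line ROI placed longitudinally in each of the five dorsal neck muscles
(trapezius TR, splenius capitis SP, semispinalis capitis Scap, semispinalis
cervicis Scerv, multifidus/rotatores MF) can be tracked frame by frame while
the subject ramps their neck-extension force to a target percentage of
maximal voluntary contraction (%MVC). This package implements that analysis
chain as a tested, reusable library — validated end to end on synthetic
speckle phantoms and simulated cohorts with known ground truth, since no
subject recordings are distributed with it.

## What it computes

* **Tracking** — points sampled every other pixel along a 15 mm ROI are
  tracked with pyramidal Lucas–Kanade optical flow; each landed point is
  re-tracked backwards and dropped when its forward–backward error exceeds
  2 px; a least-squares 1-D similarity fit of the surviving points updates
  the ROI endpoints. The per-frame Lagrangian strain is
  `e_k = 100 · (L_k − L_0) / L_0` (% of resting length; negative =
  shortening).
* **Deformation areas** — the strain-vs-time curve is integrated with the
  trapezoidal rule, `A = (Δt/2)(y_1 + 2y_2 + … + 2y_{n−1} + y_n)`, after
  inserting linearly interpolated samples at 0%-line crossings, so the
  elongation (positive-lobe) and shortening (negative-lobe magnitude)
  areas separate exactly and `total = elongation + shortening`.
* **Interaction features** — the 10 base variables (5 muscles ×
  {elongation, shortening} trial-mean areas, time- and 100%-MVC-normalised)
  are z-scored and multiplied pairwise, `i_ab = z_a ∘ z_b`, giving the
  C(10,2) = 45 two-way muscle-interaction terms.
* **Multivariate models** — PCA for exploration; OPLS (one predictive +
  one orthogonal component) regressing the interactions on %MVC, with
  leave-one-subject-out cross-validation reporting `R²Y`, `Q²Y = 1 −
  PRESS/TSS` and RMSECV, plus VIP variable importances (`mean(VIP²) = 1`;
  VIP > 1 = important).
* **Univariate statistics** — per-subject linear vs quadratic fits of
  deformation area on %MVC compared on adjusted R² with strength
  categories (weak 0.1–0.3 / moderate / strong / very strong > 0.9);
  test–retest ICC(2,1) with 95% CI and Fleiss categories; one-way
  repeated-measures ANOVA with Mauchly sphericity test and
  Greenhouse–Geisser correction.
* **Synthetic data** — speckle phantoms (blurred-noise texture stretched by
  a known ramp–hold–release strain profile at 50 frames/s) and simulated
  20-subject cohorts with planted linear/quadratic force–deformation
  relationships, muscle-specific activation profiles, subject scaling and
  trial noise.

## Worked example

```python
import numpy as np
from specklestrain import (
    PhantomSpec, ImageSequence, generate_strain_profile,
    generate_speckle_sequence, init_roi, track_sequence,
)

spec = PhantomSpec(additive_noise_sd=5.0, seed=42)      # 486x418 px, 50 fps, 6 s
profile = generate_strain_profile(spec, target_strain_pct=10.0)
frames, truth = generate_speckle_sequence(spec, profile)

seq = ImageSequence(frames, spec.fps, spec.mm_per_px)
centre = (sum(spec.band_rows) / 2, (spec.width_px - 1) / 2)
roi = init_roi(frames[0], centre, angle_deg=0.0, length_mm=15.0,
               mm_per_px=spec.mm_per_px)
series, prov = track_sequence(seq, roi)

print(roi.points.shape[0])                               # 83
print(round(series.strain_pct[np.argmax(truth)], 2))     # 10.02
print(round(np.max(np.abs(series.strain_pct - truth)), 2))  # 0.08
```

The 15 mm ROI at this resolution carries 83 tracking points; on a noisy
phantom with a planted +10% peak strain the tracked peak comes back as
10.02% and the whole 300-frame strain curve stays within 0.08 percentage
points of the ground truth.

The cohort branch runs from the command line:

```bash
specklestrain mva --seed 1 --out run/
```

which simulates a cohort, builds the 45 interaction terms and prints the
OPLS summary (for seed 1: `R2Y 0.508`, `Q2Y 0.388`, `RMSECV 20.0` %MVC) —
a monotone interaction→force structure recovered across held-out subjects.

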