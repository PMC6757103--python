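"""Synthetic inputs with known ground truth.

Two generators:

* speckle phantoms — B-mode-like image sequences in which a horizontal
  muscle band is stretched by a known longitudinal strain profile, so the
  tracker's output can be compared against truth;
* cohort tables — per-subject, per-muscle, per-%MVC, per-trial deformation
  areas with a planted linear or quadratic force-deformation relationship,
  so the statistical layers can be validated end to end.

Phantom defaults follow the acquisition used for dorsal neck muscles:
50 frames/s, 486 x 418 px video, a 38 mm transducer footprint mapped to the
image width, 6 s trials with a ramp to the target force over 3 s and a hold
of about 3 s before release.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .errors import SpecError

MUSCLES = ("TR", "SP", "Scap", "Scerv", "MF")
DEFAULT_MVC_LEVELS = (10, 20, 40, 60, 80, 100)

#: Noise-free mean TOTAL areas (%.s) per muscle at 10% and 100% MVC used to
#: anchor the planted linear relationships. Chosen once to match the scale of
#: group means reported for healthy subjects (TR 19.2 -> 63.6, SP 30.7 ->
#: 159.1, Scap 47.5 -> 152.9, Scerv 57.3 -> 123.1, MF 35.8 -> 124.9).
_AREA_ANCHORS = {
    "TR": (19.2, 63.6),
    "SP": (30.7, 159.1),
    "Scap": (47.5, 152.9),
    "Scerv": (57.3, 123.1),
    "MF": (35.8, 124.9),
}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, timing and noise of a speckle phantom sequence."""

    height_px: int = 486
    width_px: int = 418
    mm_per_px: float = 38.0 / 418.0
    fps: float = 50.0
    duration_s: float = 6.0
    speckle_grain_px: float = 1.5
    additive_noise_sd: float = 0.0
    band_rows: tuple[int, int] = (160, 320)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise SpecError("image dimensions must be positive")
        if self.fps <= 0 or self.duration_s <= 0 or self.mm_per_px <= 0:
            raise SpecError("fps, duration_s and mm_per_px must be positive")
        top, bottom = self.band_rows
        if not (0 <= top < bottom <= self.height_px):
            raise SpecError("band_rows must lie inside the image")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass(frozen=True)
class StrainProfile:
    """Per-frame true longitudinal strain, % of initial length (+ = elongation)."""

    strain_pct: np.ndarray
    ramp_s: float
    hold_s: float
    target_strain_pct: float

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain_pct, dtype=float)
        object.__setattr__(self, "strain_pct", strain)
        if strain.ndim != 1 or strain.size < 1:
            raise SpecError("strain profile must be a 1-D array")
        if strain[0] != 0.0:
            raise SpecError("strain at frame 0 must be 0")

    def __len__(self) -> int:
        return self.strain_pct.size


def generate_strain_profile(
    spec: PhantomSpec,
    target_strain_pct: float,
    ramp_s: float = 3.0,
    hold_s: float = 2.0,
) -> StrainProfile:
    """Ramp-hold-release strain profile.

    Piecewise linear: 0 -> target over ``ramp_s``, constant for ``hold_s``,
    then a linear return to 0 by the end of the trial. Mirrors the force
    task (ramp to the target level, hold ~3 s, return to rest).
    """
    if ramp_s < 0 or hold_s < 0:
        raise SpecError("ramp_s and hold_s must be non-negative")
    if ramp_s + hold_s > spec.duration_s:
        raise SpecError(
            f"ramp ({ramp_s} s) + hold ({hold_s} s) exceed trial duration "
            f"({spec.duration_s} s)"
        )
    n = spec.n_frames
    t = np.arange(n) / spec.fps
    release_s = spec.duration_s - ramp_s - hold_s
    strain = np.zeros(n)
    rising = t < ramp_s
    if ramp_s > 0:
        strain[rising] = target_strain_pct * t[rising] / ramp_s
    holding = (t >= ramp_s) & (t < ramp_s + hold_s)
    strain[holding] = target_strain_pct
    falling = t >= ramp_s + hold_s
    if release_s > 0:
        strain[falling] = target_strain_pct * (spec.duration_s - t[falling]) / release_s
    else:
        strain[falling] = target_strain_pct
    strain[0] = 0.0
    return StrainProfile(strain, ramp_s, hold_s, target_strain_pct)


# ---------------------------------------------------------------------------
# speckle phantom
# ---------------------------------------------------------------------------

def _speckle_texture(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Band-limited random texture: blurred white noise, rescaled to [0, 255]."""
    noise = rng.random((spec.height_px, spec.width_px))
    tex = ndimage.gaussian_filter(noise, sigma=spec.speckle_grain_px)
    tex -= tex.min()
    peak = tex.max()
    if peak > 0:
        tex /= peak
    return tex * 255.0


def generate_speckle_sequence(
    spec: PhantomSpec, profile: StrainProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom sequence deformed by a known strain profile.

    Frame 0 is a blurred-noise speckle texture. Frame k resamples frame 0
    under a horizontal stretch of (1 + strain_k/100) about the band centre,
    applied only to rows inside ``band_rows`` (inverse-mapped bilinear
    interpolation, so the ground truth is sub-pixel exact). Additive
    Gaussian noise is drawn independently per frame.

    Returns ``(frames, true_strain_pct)`` with frames shaped
    (n_frames, height, width), dtype uint8.
    """
    if len(profile) != spec.n_frames:
        raise SpecError(
            f"profile has {len(profile)} frames, spec implies {spec.n_frames}"
        )
    rng = np.random.default_rng(spec.seed)
    base = _speckle_texture(spec, rng)
    rows = np.arange(spec.height_px)
    cols = np.arange(spec.width_px, dtype=float)
    centre = (spec.width_px - 1) / 2.0
    top, bottom = spec.band_rows
    band = (rows >= top) & (rows < bottom)

    frames = np.empty((spec.n_frames, spec.height_px, spec.width_px), dtype=np.uint8)
    for k, s in enumerate(profile.strain_pct):
        if s == 0.0:
            img = base.copy()
        else:
            # inverse map: output col c samples source col centre + (c-centre)/(1+s/100)
            src_cols = centre + (cols - centre) / (1.0 + s / 100.0)
            img = base.copy()
            band_img = ndimage.map_coordinates(
                base,
                np.broadcast_arrays(
                    rows[band][:, None].astype(float),
                    src_cols[None, :],
                ),
                order=1,
                mode="nearest",
            )
            img[band] = band_img
        if spec.additive_noise_sd > 0:
            img = img + rng.normal(0.0, spec.additive_noise_sd, img.shape)
        frames[k] = np.clip(img, 0, 255).astype(np.uint8)
    return frames, profile.strain_pct.copy()


def write_sequence(
    path: str | Path, frames: np.ndarray, spec: PhantomSpec, profile: StrainProfile
) -> Path:
    """Write a multi-page 8-bit TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "fps": spec.fps,
                "mm_per_px": spec.mm_per_px,
                "seed": spec.seed,
                "band_rows": list(spec.band_rows),
                "true_strain_pct": profile.strain_pct.tolist(),
                "target_strain_pct": profile.target_strain_pct,
                "ramp_s": profile.ramp_s,
                "hold_s": profile.hold_s,
            },
            indent=1,
        )
    )
    return path


def read_sequence(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF and its JSON sidecar."""
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return frames, meta


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a simulated force-deformation cohort.

    ``relationship`` assigns each subject a planted shape for mean total
    area vs %MVC: "linear" (area rises proportionally with force) or
    "quadratic" (area rises with the square of force). The default mix of
    11 linear / 9 quadratic out of 20 reflects the roughly even split seen
    in healthy cohorts. Per-subject scale factors model the large
    between-subject spread of deformation magnitudes (lognormal, cv ~0.65
    as in group tables of healthy necks); trial noise models test-retest
    variability.

    The monotone interaction structure is planted by the muscle-specific
    logistic shortening-to-elongation switches (``elongation_fraction``):
    shortening lobes carry their mass at low force and elongation lobes at
    high force, so products of shortening z-scores fall with %MVC and
    products of elongation z-scores rise with it.

    ``coactivation_sd`` adds subject-specific strategy variability on top:
    at each %MVC level a subject draws one shared log-scale factor for all
    shortening lobes (spread shrinking as force rises) and one for all
    elongation lobes (spread growing with force), emulating the way a
    subject may favour overall shortening on one occasion and elongation on
    another. Set it to 0 for a clean planted-signal cohort.
    """

    n_subjects: int = 20
    mvc_levels: tuple[int, ...] = DEFAULT_MVC_LEVELS
    n_trials: int = 3
    relationship: tuple[str, ...] | str = "mixed"
    subject_scale_sd: float = 0.6
    coactivation_sd: float = 0.15
    trial_noise_sd: float = 10.0
    elapsed_mean_s: float = 8.0
    elapsed_sd_s: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SpecError("n_subjects must be >= 2")
        levels = tuple(self.mvc_levels)
        if any(not (0 < lv <= 100) for lv in levels) or list(levels) != sorted(
            set(levels)
        ):
            raise SpecError("mvc_levels must be strictly increasing in (0, 100]")
        object.__setattr__(self, "mvc_levels", levels)
        if self.trial_noise_sd < 0:
            raise SpecError("trial_noise_sd must be >= 0")
        if self.n_trials < 2:
            raise SpecError("n_trials must be >= 2")
        rel = self.relationship
        if isinstance(rel, str):
            if rel not in ("linear", "quadratic", "mixed"):
                raise SpecError("relationship must be linear, quadratic or mixed")
        else:
            rel = tuple(rel)
            if len(rel) != self.n_subjects or any(
                r not in ("linear", "quadratic") for r in rel
            ):
                raise SpecError(
                    "per-subject relationship list must have one entry "
                    "('linear'/'quadratic') per subject"
                )
            object.__setattr__(self, "relationship", rel)

    def shapes(self) -> tuple[str, ...]:
        """Resolved per-subject relationship shapes."""
        if isinstance(self.relationship, tuple):
            return self.relationship
        if self.relationship == "mixed":
            n_lin = int(round(self.n_subjects * 11 / 20))
            return ("linear",) * n_lin + ("quadratic",) * (self.n_subjects - n_lin)
        return (self.relationship,) * self.n_subjects


def expected_total_area(muscle: str, mvc_pct: float, shape: str) -> float:
    """Planted noise-free mean total area (%.s) for one muscle at one level.

    Linear: an affine ramp through the per-muscle anchors at 10% and 100%
    MVC. Quadratic: same endpoints but rising with (%MVC)^2, i.e. convex.
    """
    a10, a100 = _AREA_ANCHORS[muscle]
    if shape == "linear":
        return a10 + (a100 - a10) * (mvc_pct - 10.0) / 90.0
    if shape == "quadratic":
        return a10 + (a100 - a10) * (mvc_pct**2 - 100.0) / (10000.0 - 100.0)
    raise SpecError(f"unknown relationship shape {shape!r}")


#: Midpoint (as a fraction of the 10-100% MVC range) of each muscle's
#: shortening-to-elongation switch. The deep segmental muscles (semispinalis
#: cervicis, multifidus) switch early — their deformation peaks near 40%
#: MVC — while the superficial trapezius and semispinalis capitis switch
#: late (60-80% MVC).
ACTIVATION_MIDPOINTS = {
    "TR": 0.65,
    "SP": 0.50,
    "Scap": 0.60,
    "Scerv": 0.30,
    "MF": 0.40,
}
ACTIVATION_STEEPNESS = 12.0


def elongation_fraction(mvc_pct: float, muscle: str = "SP") -> float:
    """Share of total area that is elongation for one muscle at one level.

    A logistic switch from shortening-dominated (share 0.12) to
    elongation-dominated (share 0.90) deformation, centred at a
    muscle-specific force level: low-force contractions show mostly
    shortening while near-maximal effort is dominated by elongation
    (passive stretch of neighbours and forward drift of the spine), and
    deep muscles make the switch at lower force than superficial ones.
    """
    r = (mvc_pct - 10.0) / 90.0
    r0 = ACTIVATION_MIDPOINTS[muscle]
    return float(0.12 + 0.78 / (1.0 + np.exp(-ACTIVATION_STEEPNESS * (r - r0))))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a long-format subject table.

    One row per subject x muscle x %MVC x trial with columns
    ``subject, muscle, mvc_pct, trial, elong_area, short_area, total_area,
    elapsed_s``. Noise-free totals follow the subject's planted
    relationship; Gaussian trial noise is added to each lobe and truncated
    at zero (areas are magnitudes), so total = elong + short holds exactly
    by construction. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    shapes = spec.shapes()
    # lognormal positive subject scales, median 1
    scales = np.exp(rng.normal(0.0, spec.subject_scale_sd, spec.n_subjects))
    lo, hi = spec.mvc_levels[0], spec.mvc_levels[-1]
    span = max(hi - lo, 1)
    rows = []
    for s_idx in range(spec.n_subjects):
        subject = s_idx + 1
        for mvc in spec.mvc_levels:
            # per-level co-activation: one shared factor per lobe kind,
            # shortening coherence fading and elongation coherence growing
            # with force
            ramp = (mvc - lo) / span
            f_elong = np.exp(rng.normal(0.0, spec.coactivation_sd * ramp))
            f_short = np.exp(rng.normal(0.0, spec.coactivation_sd * (1.0 - ramp)))
            for muscle in MUSCLES:
                mean_total = scales[s_idx] * expected_total_area(
                    muscle, mvc, shapes[s_idx]
                )
                frac = elongation_fraction(mvc, muscle)
                for trial in range(1, spec.n_trials + 1):
                    elong = max(
                        0.0,
                        mean_total * frac * f_elong
                        + rng.normal(0.0, spec.trial_noise_sd),
                    )
                    short = max(
                        0.0,
                        mean_total * (1 - frac) * f_short
                        + rng.normal(0.0, spec.trial_noise_sd),
                    )
                    elapsed = max(
                        1.0, rng.normal(spec.elapsed_mean_s, spec.elapsed_sd_s)
                    )
                    rows.append(
                        (
                            subject,
                            muscle,
                            mvc,
                            trial,
                            elong,
                            short,
                            elong + short,
                            elapsed,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "muscle",
            "mvc_pct",
            "trial",
            "elong_area",
            "short_area",
            "total_area",
            "elapsed_s",
        ],
    )


def write_cohort(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
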