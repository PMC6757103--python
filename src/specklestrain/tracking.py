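"""Speckle tracking of muscle ROIs and Lagrangian strain extraction.

A 15 mm line ROI is placed longitudinally in the muscle and sampled at
every other pixel. Points are tracked frame to frame with a pyramidal
Lucas-Kanade optical-flow estimator; every landed point is re-tracked
backwards and the distance to its original position (the forward-backward
error) flags unreliable tracks, which are dropped for all later frames.
Surviving points, in correspondence with their frame-0 positions, drive a
least-squares 1-D similarity fit that updates the ROI endpoints; the ROI
length per frame gives the Lagrangian strain

    strain_k = 100 * (L_k - L_0) / L_0   [% of resting length]

with positive values meaning elongation and negative values shortening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PlacementError, SpecError, TrackingLostError


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSequence:
    frames: np.ndarray  # (n_frames, h, w) grayscale
    fps: float
    mm_per_px: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[0] < 2:
            raise SpecError("need >= 2 frames of identical shape")
        if self.fps <= 0 or self.mm_per_px <= 0:
            raise SpecError("fps and mm_per_px must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class ROI:
    """A line segment ROI with its in-segment tracking points.

    Coordinates are (row, col), 0-based, at pixel centres; lengths are kept
    in pixels and converted through mm_per_px only when reporting.
    """

    endpoints: np.ndarray  # (2, 2) [(r0,c0),(r1,c1)]
    points: np.ndarray  # (n, 2)
    length_mm: float
    point_spacing_px: float = 2.0

    @property
    def length_px(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from endpoint 0 to endpoint 1."""
        d = self.endpoints[1] - self.endpoints[0]
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class TrackerParams:
    window_px: int = 15
    pyramid_levels: int = 3
    max_iterations: int = 30
    convergence_eps_px: float = 0.01
    fb_threshold_px: float = 2.0
    min_eig_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise SpecError("window_px must be odd and >= 3")
        if self.fb_threshold_px <= 0:
            raise SpecError("fb_threshold_px must be positive")


@dataclass
class TrackedFrame:
    points: np.ndarray  # (n, 2) current positions
    fb_error_px: np.ndarray  # (n,) forward-backward error, inf if invalid
    valid: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        n = self.points.shape[0]
        if self.fb_error_px.shape != (n,) or self.valid.shape != (n,):
            raise SpecError("TrackedFrame arrays must share one length")
        if np.any(self.fb_error_px < 0):
            raise SpecError("forward-backward errors must be >= 0")


@dataclass(frozen=True)
class StrainSeries:
    """Per-frame % deformation relative to the first-frame ROI length."""

    strain_pct: np.ndarray
    reference_length_px: float
    fps: float

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain_pct, dtype=float)
        object.__setattr__(self, "strain_pct", strain)
        if strain.size == 0 or strain[0] != 0.0:
            raise SpecError("strain series must start at exactly 0")
        if not np.all(np.isfinite(strain)):
            raise SpecError("strain series must be finite")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.strain_pct.size) / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.strain_pct.size),
                "time_s": self.time_s,
                "strain_pct": self.strain_pct,
            }
        )


# ---------------------------------------------------------------------------
# ROI placement
# ---------------------------------------------------------------------------

def init_roi(
    image: np.ndarray,
    center_px: tuple[float, float],
    angle_deg: float,
    length_mm: float,
    mm_per_px: float,
    point_spacing_px: float = 2.0,
) -> ROI:
    """Place a line ROI and sample tracking points along it.

    The segment is centred on ``center_px`` (row, col) at ``angle_deg``
    (0 = along image columns). Points are sampled every
    ``point_spacing_px`` pixels from one endpoint, endpoint included, i.e.
    floor(length_px / spacing) + 1 points.
    """
    if length_mm <= 0:
        raise SpecError("length_mm must be positive")
    if point_spacing_px <= 0:
        raise SpecError("point_spacing_px must be positive")
    length_px = length_mm / mm_per_px
    theta = np.deg2rad(angle_deg)
    direction = np.array([np.sin(theta), np.cos(theta)])  # (drow, dcol)
    centre = np.asarray(center_px, dtype=float)
    half = direction * length_px / 2.0
    endpoints = np.stack([centre - half, centre + half])
    h, w = image.shape[:2]
    if np.any(endpoints < 0) or np.any(endpoints[:, 0] > h - 1) or np.any(
        endpoints[:, 1] > w - 1
    ):
        raise PlacementError(
            f"ROI endpoints {endpoints.tolist()} leave the {h}x{w} image"
        )
    n_points = int(np.floor(length_px / point_spacing_px)) + 1
    offsets = np.arange(n_points) * point_spacing_px
    points = endpoints[0] + offsets[:, None] * direction
    return ROI(endpoints, points, length_mm, point_spacing_px)


# ---------------------------------------------------------------------------
# pyramidal Lucas-Kanade
# ---------------------------------------------------------------------------

def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    """Gaussian pyramid, level 0 = full resolution."""
    pyr = [np.asarray(img, dtype=float)]
    for _ in range(1, levels):
        smoothed = ndimage.gaussian_filter(pyr[-1], sigma=1.0)
        pyr.append(smoothed[::2, ::2])
    return pyr


def _gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gr, gc = np.gradient(img)
    return gr, gc


def _sample(img: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Bilinear sample at (n, 2) (row, col) float coords."""
    return ndimage.map_coordinates(img, coords.T, order=1, mode="nearest")


def _lk_level(
    prev: np.ndarray,
    prev_gr: np.ndarray,
    prev_gc: np.ndarray,
    next_: np.ndarray,
    pts: np.ndarray,
    guess: np.ndarray,
    params: TrackerParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One pyramid level of iterative LK for all points at once.

    Returns (displacements, valid). Template windows and normal matrices
    are fixed per level; the residual against the moving window is
    re-evaluated each iteration.
    """
    n = pts.shape[0]
    half = params.window_px // 2
    dr, dc = np.meshgrid(
        np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij"
    )
    offsets = np.stack([dr.ravel(), dc.ravel()], axis=1)  # (w2, 2)
    # (n, w2, 2) absolute template coordinates
    win = pts[:, None, :] + offsets[None, :, :]
    h, w = prev.shape
    inside = (
        (win[..., 0] >= 0)
        & (win[..., 0] <= h - 1)
        & (win[..., 1] >= 0)
        & (win[..., 1] <= w - 1)
    ).all(axis=1)

    flat = win.reshape(-1, 2)
    t_val = _sample(prev, flat).reshape(n, -1)
    t_gr = _sample(prev_gr, flat).reshape(n, -1)
    t_gc = _sample(prev_gc, flat).reshape(n, -1)

    g_rr = np.sum(t_gr * t_gr, axis=1)
    g_rc = np.sum(t_gr * t_gc, axis=1)
    g_cc = np.sum(t_gc * t_gc, axis=1)
    det = g_rr * g_cc - g_rc * g_rc
    trace = g_rr + g_cc
    min_eig = (trace - np.sqrt(np.maximum(trace**2 - 4 * det, 0.0))) / 2.0
    win_area = offsets.shape[0]
    conditioned = min_eig / win_area > params.min_eig_threshold

    valid = inside & conditioned
    disp = guess.copy()
    active = valid.copy()
    for _ in range(params.max_iterations):
        if not active.any():
            break
        cur = win[active] + disp[active][:, None, :]
        out = (
            (cur[..., 0] < 0)
            | (cur[..., 0] > h - 1)
            | (cur[..., 1] < 0)
            | (cur[..., 1] > w - 1)
        ).any(axis=1)
        idx = np.flatnonzero(active)
        valid[idx[out]] = False
        active[idx[out]] = False
        if not active.any():
            break
        cur = win[active] + disp[active][:, None, :]
        n_val = _sample(next_, cur.reshape(-1, 2)).reshape(cur.shape[0], -1)
        err = n_val - t_val[active]
        b_r = np.sum(err * t_gr[active], axis=1)
        b_c = np.sum(err * t_gc[active], axis=1)
        d = det[active]
        delta_r = -(g_cc[active] * b_r - g_rc[active] * b_c) / d
        delta_c = -(-g_rc[active] * b_r + g_rr[active] * b_c) / d
        step = np.stack([delta_r, delta_c], axis=1)
        disp[active] += step
        converged = np.linalg.norm(step, axis=1) < params.convergence_eps_px
        idx = np.flatnonzero(active)
        active[idx[converged]] = False
    return disp, valid


def _lk_pyramidal(
    prev_pyr: list[np.ndarray],
    prev_grads: list[tuple[np.ndarray, np.ndarray]],
    next_pyr: list[np.ndarray],
    pts: np.ndarray,
    params: TrackerParams,
) -> tuple[np.ndarray, np.ndarray]:
    levels = len(prev_pyr)
    disp = np.zeros_like(pts)
    valid = np.ones(pts.shape[0], dtype=bool)
    for level in range(levels - 1, -1, -1):
        scale = 2.0**level
        d, v = _lk_level(
            prev_pyr[level],
            prev_grads[level][0],
            prev_grads[level][1],
            next_pyr[level],
            pts / scale,
            disp / scale,
            params,
        )
        # points invalid at a coarse level (window near the shrunken image
        # border, weak coarse texture) keep their current guess and get
        # refined at finer levels; only full-resolution validity is final
        disp = np.where(v[:, None], d * scale, disp)
        if level == 0:
            valid &= v
    return disp, valid


def track_points(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    points: np.ndarray,
    params: TrackerParams | None = None,
    *,
    _prev_pyr=None,
    _prev_grads=None,
    _next_pyr=None,
    _next_grads=None,
) -> TrackedFrame:
    """Track points one frame forward with pyramidal LK + FB error.

    Each landed point is tracked back to ``prev_frame`` and the Euclidean
    distance to its original position is its forward-backward error. Points
    whose window leaves the image or sits on structureless texture are
    marked invalid with infinite error rather than raising.
    """
    params = params or TrackerParams()
    if prev_frame.shape != next_frame.shape:
        raise SpecError("frames must share one shape")
    pts = np.asarray(points, dtype=float)
    prev_pyr = _prev_pyr if _prev_pyr is not None else _pyramid(prev_frame, params.pyramid_levels)
    next_pyr = _next_pyr if _next_pyr is not None else _pyramid(next_frame, params.pyramid_levels)
    prev_grads = _prev_grads if _prev_grads is not None else [_gradients(p) for p in prev_pyr]
    next_grads = _next_grads if _next_grads is not None else [_gradients(p) for p in next_pyr]

    disp, valid = _lk_pyramidal(prev_pyr, prev_grads, next_pyr, pts, params)
    landed = pts + disp
    back_disp, back_valid = _lk_pyramidal(next_pyr, next_grads, prev_pyr, landed, params)
    fb = np.linalg.norm(landed + back_disp - pts, axis=1)
    ok = valid & back_valid
    fb = np.where(ok, fb, np.inf)
    return TrackedFrame(points=landed, fb_error_px=fb, valid=ok)


def filter_tracked(tracked: TrackedFrame, fb_threshold_px: float = 2.0) -> TrackedFrame:
    """Drop points whose forward-backward error exceeds the threshold.

    Original indices are preserved (the valid mask shrinks), keeping
    correspondence with the frame-0 points. Raises ``TrackingLostError``
    when fewer than two points survive.
    """
    if fb_threshold_px <= 0:
        raise SpecError("fb_threshold_px must be positive")
    keep = tracked.valid & (tracked.fb_error_px <= fb_threshold_px)
    if keep.sum() < 2:
        raise TrackingLostError(
            f"only {int(keep.sum())} reliable point(s) survive FB filtering"
        )
    return TrackedFrame(
        points=tracked.points, fb_error_px=tracked.fb_error_px, valid=keep
    )


# ---------------------------------------------------------------------------
# ROI update and strain
# ---------------------------------------------------------------------------

def update_roi(
    initial_points: np.ndarray,
    current_points: np.ndarray,
    initial_endpoints: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Least-squares 1-D similarity update of the ROI endpoints.

    Both point sets are projected onto the initial ROI axis; (scale s,
    shift u) minimising sum((s*x0 + u - x1)^2) is applied to the endpoint
    projections. Only longitudinal length matters for strain, so the
    transverse coordinate is carried over unchanged. Returns the new
    endpoints and the new length in pixels (= s * initial length).
    """
    p0 = np.asarray(initial_points, dtype=float)
    p1 = np.asarray(current_points, dtype=float)
    if p0.shape != p1.shape or p0.shape[0] < 2:
        raise SpecError("need >= 2 corresponding points")
    e0 = np.asarray(initial_endpoints, dtype=float)
    axis = e0[1] - e0[0]
    length0 = np.linalg.norm(axis)
    axis = axis / length0
    x0 = (p0 - e0[0]) @ axis
    x1 = (p1 - e0[0]) @ axis
    if np.ptp(x0) == 0:
        raise SpecError("initial points are degenerate along the ROI axis")
    design = np.stack([x0, np.ones_like(x0)], axis=1)
    (s, u), *_ = np.linalg.lstsq(design, x1, rcond=None)
    # transverse drift: mean perpendicular displacement carried to endpoints
    perp = np.array([-axis[1], axis[0]])
    drift = float(np.mean((p1 - p0) @ perp))
    proj_e = (e0 - e0[0]) @ axis
    new_endpoints = (
        e0[0]
        + (s * proj_e + u)[:, None] * axis
        + drift * perp
    )
    return new_endpoints, float(s * length0)


def strain_series(lengths_px: np.ndarray, fps: float) -> StrainSeries:
    """Lagrangian strain from per-frame ROI lengths.

    strain_k = 100 * (L_k - L_0) / L_0, frame 0 being the resting
    reference; the sequential frame-to-frame tracking means each L_k is the
    cumulative deformation history.
    """
    lengths = np.asarray(lengths_px, dtype=float)
    if lengths.size == 0 or lengths[0] <= 0:
        raise SpecError("reference length must be positive")
    strain = 100.0 * (lengths - lengths[0]) / lengths[0]
    strain[0] = 0.0
    return StrainSeries(strain, float(lengths[0]), fps)


def track_sequence(
    sequence: ImageSequence,
    roi: ROI,
    params: TrackerParams | None = None,
) -> tuple[StrainSeries, dict]:
    """Track an ROI through a whole sequence and return its strain series.

    Sequential (k -> k+1) tracking with correspondence kept to frame 0: a
    point removed by the FB filter in any frame is excluded from all later
    frames, so the similarity fit always maps frame-0 positions onto
    current positions of the same physical points.
    """
    params = params or TrackerParams()
    frames = sequence.frames
    n = len(sequence)
    alive = np.ones(roi.points.shape[0], dtype=bool)
    positions = roi.points.copy()
    lengths = np.empty(n)
    lengths[0] = roi.length_px
    survivors = [int(alive.sum())]

    prev_pyr = _pyramid(frames[0], params.pyramid_levels)
    prev_grads = [_gradients(p) for p in prev_pyr]
    for k in range(1, n):
        next_pyr = _pyramid(frames[k], params.pyramid_levels)
        next_grads = [_gradients(p) for p in next_pyr]
        tracked = track_points(
            frames[k - 1],
            frames[k],
            positions[alive],
            params,
            _prev_pyr=prev_pyr,
            _prev_grads=prev_grads,
            _next_pyr=next_pyr,
            _next_grads=next_grads,
        )
        try:
            kept = filter_tracked(tracked, params.fb_threshold_px)
        except TrackingLostError as exc:
            raise TrackingLostError(f"frame {k}: {exc}") from exc
        idx = np.flatnonzero(alive)
        positions[idx] = tracked.points
        alive[idx[~kept.valid]] = False
        if alive.sum() < 2:
            raise TrackingLostError(f"frame {k}: fewer than 2 surviving points")
        _, length = update_roi(
            roi.points[alive], positions[alive], roi.endpoints
        )
        lengths[k] = length
        survivors.append(int(alive.sum()))
        prev_pyr, prev_grads = next_pyr, next_grads

    series = strain_series(lengths, sequence.fps)
    provenance = {
        "roi_endpoints": roi.endpoints.tolist(),
        "n_points_initial": int(roi.points.shape[0]),
        "surviving_points": survivors,
        "params": {
            "window_px": params.window_px,
            "pyramid_levels": params.pyramid_levels,
            "max_iterations": params.max_iterations,
            "convergence_eps_px": params.convergence_eps_px,
            "fb_threshold_px": params.fb_threshold_px,
        },
    }
    return series, provenance


def write_strain(path: str | Path, series: StrainSeries, provenance: dict) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(provenance, indent=1))
    return path
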