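"""Deformation-area statistics of strain-vs-time curves.

The area under a deformation curve over the whole trial summarises how much
a muscle deformed; the composite trapezoidal rule

    A = (dt/2) * (y_1 + 2 y_2 + ... + 2 y_{n-1} + y_n)

gives the signed area in %.s. Because a muscle can switch between
shortening (negative strain) and elongation (positive strain) within one
trial, the curve is split at its 0%-line crossings — extra samples are
inserted at linearly interpolated times — so the positive and negative
lobes can be integrated separately. Elongation and shortening areas are
reported as magnitudes; their sum is the total deformation area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError, SpecError

MUSCLES = ("TR", "SP", "Scap", "Scerv", "MF")


@dataclass(frozen=True)
class DeformationCurve:
    """Sampled % deformation values at a fixed sampling interval dt (s)."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise SpecError("a curve needs at least 2 samples")
        if self.dt <= 0:
            raise SpecError("dt must be positive")


@dataclass(frozen=True)
class AreaDecomposition:
    """Elongation/shortening/total areas of one curve, all >= 0, in %.s."""

    elongation_area: float
    shortening_area: float

    @property
    def total_area(self) -> float:
        return self.elongation_area + self.shortening_area


def trapezoid_area(curve: DeformationCurve) -> float:
    """Signed trapezoid area of the curve, in %.s."""
    return float(np.trapezoid(curve.values, dx=curve.dt))


def _insert_zero_crossings(values: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample times and values with extra points at interpolated 0-crossings."""
    t = np.arange(values.size) * dt
    y0, y1 = values[:-1], values[1:]
    crossing = (y0 * y1) < 0  # strict sign change; exact zeros are boundaries
    if not crossing.any():
        return t, values
    idx = np.flatnonzero(crossing)
    t_cross = t[idx] + dt * y0[idx] / (y0[idx] - y1[idx])
    t_all = np.concatenate([t, t_cross])
    y_all = np.concatenate([values, np.zeros(t_cross.size)])
    order = np.argsort(t_all, kind="stable")
    return t_all[order], y_all[order]


def split_signed_areas(curve: DeformationCurve) -> AreaDecomposition:
    """Split the signed area into elongation and shortening lobes.

    Zero crossings between samples of opposite sign are inserted at their
    linearly interpolated times, after which every trapezoid lies entirely
    in one lobe. Samples exactly at 0% are lobe boundaries and contribute
    no area to either side.
    """
    t, y = _insert_zero_crossings(curve.values, curve.dt)
    seg = 0.5 * (y[:-1] + y[1:]) * np.diff(t)
    elong = float(seg[seg > 0].sum())
    short = float(-seg[seg < 0].sum())
    return AreaDecomposition(elongation_area=elong, shortening_area=short)


# ---------------------------------------------------------------------------
# table-level aggregation
# ---------------------------------------------------------------------------

_REQUIRED = ["subject", "muscle", "mvc_pct", "trial", "elong_area", "short_area"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise SpecError(f"subject table lacks columns: {missing}")


def aggregate_trials(table: pd.DataFrame, time_normalize: bool = False) -> pd.DataFrame:
    """Mean areas per subject x muscle x %MVC over the available trials.

    With ``time_normalize`` each trial's areas are first divided by that
    trial's elapsed time (the multivariate branch); otherwise raw areas are
    averaged (the curve-fitting branch). Cells must hold 2 or 3 trials —
    occasionally only two are recorded — and a cell with fewer raises
    ``MissingDataError`` naming it.
    """
    _check_table(table)
    work = table.copy()
    if time_normalize:
        if "elapsed_s" not in work.columns:
            raise SpecError("time_normalize requires an elapsed_s column")
        for col in ("elong_area", "short_area"):
            work[col] = work[col] / work["elapsed_s"]
    counts = work.groupby(["subject", "muscle", "mvc_pct"]).size()
    bad = counts[counts < 2]
    if len(bad):
        cells = ", ".join(str(ix) for ix in bad.index.tolist()[:5])
        raise MissingDataError(f"cells with fewer than 2 trials: {cells}")
    out = (
        work.groupby(["subject", "muscle", "mvc_pct"], as_index=False)[
            ["elong_area", "short_area"]
        ]
        .mean()
    )
    out["total_area"] = out["elong_area"] + out["short_area"]
    return out


def sum_muscles(means: pd.DataFrame) -> pd.DataFrame:
    """Sum areas over the five muscles per subject x %MVC."""
    out = (
        means.groupby(["subject", "mvc_pct"], as_index=False)[
            ["elong_area", "short_area", "total_area"]
        ]
        .sum()
    )
    return out


def normalize_to_mvc(
    means: pd.DataFrame,
    value_cols: tuple[str, ...] = ("elong_area", "short_area", "total_area"),
    per_muscle: bool = True,
) -> pd.DataFrame:
    """Divide each subject's values by that subject's 100% MVC total area.

    Per-muscle references by default; with ``per_muscle=False`` a single
    five-muscle-summed reference per subject is used. The reference cell
    itself maps to 1 (on total_area). Raises when a subject lacks a
    positive 100% MVC reference.
    """
    keys = ["subject", "muscle"] if per_muscle and "muscle" in means.columns else ["subject"]
    ref_rows = means[means["mvc_pct"] == 100]
    if per_muscle and "muscle" in means.columns:
        ref = ref_rows.groupby(keys)["total_area"].sum()
    else:
        ref = ref_rows.groupby("subject")["total_area"].sum()
    subjects = means["subject"].unique()
    missing = [s for s in subjects if s not in ref.index.get_level_values(0)]
    if missing:
        raise MissingDataError(f"no 100% MVC reference for subject(s) {missing}")
    if (ref <= 0).any():
        bad = ref[ref <= 0].index.tolist()
        raise MissingDataError(f"zero 100% MVC reference for {bad}")
    out = means.copy()
    denom = means.set_index(keys).index.map(ref)
    for col in value_cols:
        out[col] = means[col].to_numpy() / denom.to_numpy()
    return out


def decompose_series(strain_pct: np.ndarray, fps: float) -> AreaDecomposition:
    """Convenience: area decomposition of a tracked strain series."""
    return split_signed_areas(DeformationCurve(np.asarray(strain_pct), 1.0 / fps))
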