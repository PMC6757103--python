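"""Two-way muscle-interaction features and multivariate preprocessing.

Ten base variables per observation (subject x %MVC): the trial-mean
elongation and shortening areas of the five dorsal neck muscles, each trial
divided by its elapsed time and, in the default pipeline, by the subject's
100% MVC reference so deformations are comparable across individuals.
Each base column is standardised (z-scored) and all C(10,2) = 45 unordered
pairs are multiplied element-wise,

    i_ab = (a - mean_a)/sd_a * (b - mean_b)/sd_b,

giving one interaction term per muscle/lobe pair. Before latent-variable
modelling the interaction matrix passes through a signed log transform
L(x) = sign(x) * log10(1 + |x|) — products of z-scores are signed, so a
plain log10 is undefined on them; L is odd, monotone and ~log10 for large
|x| — followed by column centring and unit-variance scaling.

Observations cover the submaximal levels 10-80% MVC; the 100% MVC trials
serve only as each subject's normalisation reference elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import SpecError

BASE_COLUMNS = tuple(
    f"{muscle}_{lobe}"
    for muscle in ("TR", "SP", "Scap", "Scerv", "MF")
    for lobe in ("elo", "short")
)
SUBMAX_LEVELS = (10, 20, 40, 60, 80)


@dataclass(frozen=True)
class Standardization:
    mean: pd.Series
    sd: pd.Series


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, Standardization]:
    """Z-score each column (sample sd, ddof=1)."""
    if len(matrix) < 2:
        raise SpecError("need >= 2 rows to standardize")
    mean = matrix.mean()
    sd = matrix.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise SpecError(f"zero-variance column(s): {list(zero.index)}")
    return (matrix - mean) / sd, Standardization(mean, sd)


def base_feature_matrix(
    means: pd.DataFrame, levels: tuple[int, ...] = SUBMAX_LEVELS
) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot aggregated (time-normalised) means into the 10-column base matrix.

    Rows are subject x %MVC observations restricted to the submaximal
    levels; returns the matrix and the %MVC response aligned to it. The
    subject id is kept in the index for grouped cross-validation.
    """
    sub = means[means["mvc_pct"].isin(levels)]
    wide_e = sub.pivot(index=["subject", "mvc_pct"], columns="muscle", values="elong_area")
    wide_s = sub.pivot(index=["subject", "mvc_pct"], columns="muscle", values="short_area")
    cols = {}
    for name in BASE_COLUMNS:
        muscle, lobe = name.rsplit("_", 1)
        src = wide_e if lobe == "elo" else wide_s
        cols[name] = src[muscle]
    base = pd.DataFrame(cols)
    if base.isna().any().any():
        raise SpecError("missing subject x level cells in the base matrix")
    y = base.index.get_level_values("mvc_pct").to_series(index=base.index).astype(float)
    return base, y


def interaction_terms(matrix: pd.DataFrame) -> pd.DataFrame:
    """All 45 two-way interaction columns of the 10 base variables.

    Column names are "<colA>*<colB>" with pairs in canonical (base-column)
    order, so the layout is stable across runs.
    """
    if matrix.shape[1] != len(BASE_COLUMNS):
        raise SpecError(
            f"expected {len(BASE_COLUMNS)} base columns, got {matrix.shape[1]}"
        )
    z, _ = standardize(matrix)
    out = {}
    for a, b in combinations(matrix.columns, 2):
        out[f"{a}*{b}"] = z[a].to_numpy() * z[b].to_numpy()
    return pd.DataFrame(out, index=matrix.index)


@dataclass(frozen=True)
class PreprocessState:
    """Parameters of the signed-log / centre / scale transform."""

    mean: pd.Series
    sd: pd.Series

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "sd": self.sd.to_dict()}


def signed_log10(x: np.ndarray) -> np.ndarray:
    """Odd, monotone log transform defined on all reals: sign(x)log10(1+|x|)."""
    return np.sign(x) * np.log10(1.0 + np.abs(x))


def mva_preprocess(
    interactions: pd.DataFrame, state: PreprocessState | None = None
) -> tuple[pd.DataFrame, PreprocessState]:
    """Signed-log transform, then centre and scale to unit variance.

    When ``state`` is given (e.g. inside a cross-validation fold) its means
    and sds are applied instead of refitting, so held-out rows never leak
    into the preprocessing statistics.
    """
    logged = pd.DataFrame(
        signed_log10(interactions.to_numpy()),
        index=interactions.index,
        columns=interactions.columns,
    )
    if state is None:
        mean = logged.mean()
        sd = logged.std(ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise SpecError(
                f"zero-variance column(s) after transform: {list(zero.index)}"
            )
        state = PreprocessState(mean, sd)
    return (logged - state.mean) / state.sd, state
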