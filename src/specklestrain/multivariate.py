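"""Latent-variable models linking muscle interactions to contraction level.

PCA compresses the 45-column interaction matrix for exploratory score
plots. OPLS (orthogonal projections to latent structures) first strips
predictor variation that is orthogonal to the response — here the numeric
%MVC level treated as continuous — then fits a single predictive PLS
component, so one score axis carries all response-related variation:

    R2Y = 1 - ||y - yhat||^2 / ||y - ybar||^2          (fit)
    Q2Y = 1 - PRESS / TSS                              (cross-validated)
    RMSECV = sqrt(PRESS / n)                           (%MVC units)

Cross-validation is leave-one-subject-out: all of one subject's
observations are held out and predicted together, and the preprocessing
statistics (signed-log / centre / scale) are refit on each training fold so
nothing leaks from the held-out subject. Variable importance in projection
(VIP) ranks interaction terms by their weight in the predictive component;
values above 1 are conventionally important.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .errors import SpecError
from .features import mva_preprocess, signed_log10


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    loadings: np.ndarray  # (n_components, n_vars), orthonormal rows
    scores: np.ndarray  # (n_obs, n_components)
    explained_variance_ratio: np.ndarray


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """PCA of a centred/scaled matrix (SVD-based)."""
    X = np.asarray(X, dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if n_components > limit:
        raise SpecError(f"n_components {n_components} exceeds rank limit {limit}")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAModel(
        loadings=model.components_,
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# OPLS
# ---------------------------------------------------------------------------

@dataclass
class OPLSModel:
    """One predictive + ``n_orthogonal`` orthogonal components (NIPALS)."""

    w_pred: np.ndarray  # (p,) predictive weights, unit norm
    p_pred: np.ndarray  # (p,) predictive loadings
    t_pred: np.ndarray  # (n,) predictive scores
    q: float  # y-loading (regression of y on t_pred)
    w_orth: np.ndarray  # (k, p)
    p_orth: np.ndarray  # (k, p)
    t_orth: np.ndarray  # (n, k)
    r2y: float
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_orthogonal(self) -> int:
        return self.w_orth.shape[0]

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new observations."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        t_orth = np.empty((Xc.shape[0], self.n_orthogonal))
        for k in range(self.n_orthogonal):
            t_orth[:, k] = Xc @ self.w_orth[k]
            Xc = Xc - np.outer(t_orth[:, k], self.p_orth[k])
        return Xc @ self.w_pred, t_orth

    def predict(self, X: np.ndarray) -> np.ndarray:
        t, _ = self.transform(X)
        return t * self.q + self.y_mean


def fit_opls(X: np.ndarray, y: np.ndarray, n_orthogonal: int = 1) -> OPLSModel:
    """Fit an OPLS model with one predictive component.

    Orthogonal (y-uncorrelated) components are deflated from X first; with
    ``n_orthogonal=0`` the model reduces exactly to 1-component PLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_orthogonal < 0:
        raise SpecError("n_orthogonal must be >= 0")
    if np.std(y) == 0:
        raise SpecError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    w_orth_list, p_orth_list, t_orth_list = [], [], []
    for _ in range(n_orthogonal):
        w = Xc.T @ yc / (yc @ yc)
        w = w / np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            break  # no orthogonal variation left
        wo = wo / norm
        to = Xc @ wo
        po = Xc.T @ to / (to @ to)
        Xc = Xc - np.outer(to, po)
        w_orth_list.append(wo)
        p_orth_list.append(po)
        t_orth_list.append(to)

    w = Xc.T @ yc / (yc @ yc)
    w = w / np.linalg.norm(w)
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    resid = yc - t * q
    r2y = float(1.0 - (resid @ resid) / (yc @ yc))

    k = len(w_orth_list)
    pdim = X.shape[1]
    return OPLSModel(
        w_pred=w,
        p_pred=p,
        t_pred=t,
        q=q,
        w_orth=np.array(w_orth_list).reshape(k, pdim),
        p_orth=np.array(p_orth_list).reshape(k, pdim),
        t_orth=np.array(t_orth_list).T.reshape(len(y), k) if k else np.zeros((len(y), 0)),
        r2y=r2y,
        x_mean=x_mean,
        y_mean=y_mean,
    )


# ---------------------------------------------------------------------------
# grouped cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    q2y: float
    rmsecv: float
    predictions: pd.DataFrame  # subject, y_true, y_pred per observation
    cv_scores: pd.DataFrame  # held-out predictive / first orthogonal scores


def _fold_standardize(train: np.ndarray, test: np.ndarray, log_transform: bool):
    if log_transform:
        train = signed_log10(train)
        test = signed_log10(test)
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mean) / sd, (test - mean) / sd


def loso_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    subject_ids: np.ndarray,
    n_orthogonal: int = 1,
    log_transform: bool = False,
) -> CVResult:
    """Leave-one-subject-out cross-validation of the OPLS model.

    Per fold, every observation of one subject is held out; the column
    statistics (optionally after the signed-log transform) and the model
    are refit on the remaining subjects and the held-out responses are
    predicted. Q2Y = 1 - PRESS/TSS with TSS about the grand mean; RMSECV =
    sqrt(PRESS/n) in response units.
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    subject_ids = np.asarray(subject_ids)
    subjects = pd.unique(subject_ids)
    if len(subjects) < 3:
        raise SpecError("leave-one-subject-out needs >= 3 subjects")
    y_pred = np.empty_like(y)
    t_pred_cv = np.empty_like(y)
    t_orth_cv = np.full(len(y), np.nan)
    for subj in subjects:
        test = subject_ids == subj
        train = ~test
        if len(pd.unique(subject_ids[train])) < 2:
            raise SpecError("a fold would leave < 2 training subjects")
        X_tr, X_te = _fold_standardize(Xv[train], Xv[test], log_transform)
        model = fit_opls(X_tr, y[train], n_orthogonal)
        y_pred[test] = model.predict(X_te)
        tp, to = model.transform(X_te)
        t_pred_cv[test] = tp
        if to.shape[1]:
            t_orth_cv[test] = to[:, 0]
    press = float(np.sum((y - y_pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    q2y = 1.0 - press / tss
    rmsecv = float(np.sqrt(press / len(y)))
    predictions = pd.DataFrame(
        {"subject": subject_ids, "y_true": y, "y_pred": y_pred}
    )
    cv_scores = pd.DataFrame(
        {"subject": subject_ids, "t_pred": t_pred_cv, "t_orth": t_orth_cv}
    )
    return CVResult(q2y=q2y, rmsecv=rmsecv, predictions=predictions, cv_scores=cv_scores)


# ---------------------------------------------------------------------------
# VIP and loading classes
# ---------------------------------------------------------------------------

def plot_cv_scores(cv: CVResult, path, y: np.ndarray | None = None):
    """Scatter the cross-validated predictive vs orthogonal scores.

    One dot per held-out observation, coloured by the response (%MVC) when
    given; the canonical visual check that low- and high-force trials
    separate along the predictive axis. Writes PNG/SVG per the extension.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colour = y if y is not None else cv.predictions["y_true"]
    sc = ax.scatter(cv.cv_scores["t_pred"], cv.cv_scores["t_orth"], c=colour, cmap="viridis", s=18)
    fig.colorbar(sc, ax=ax, label="%MVC")
    ax.set_xlabel("cross-validated predictive score")
    ax.set_ylabel("cross-validated orthogonal score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


@dataclass(frozen=True)
class VIPResult:
    vip: pd.Series  # per variable
    important: pd.Series  # VIP > 1


def vip_scores(
    model: OPLSModel, columns: "list[str] | None" = None
) -> VIPResult:
    """Variable importance in projection for the predictive component.

    With a single predictive component, VIP_j = sqrt(K) * |w_j| for unit-
    norm weights, so mean(VIP^2) = 1 by construction.
    """
    w = model.w_pred
    k = w.size
    vip = np.sqrt(k * w**2 / float(w @ w))
    idx = columns if columns is not None else list(range(k))
    s = pd.Series(vip, index=idx, name="vip")
    return VIPResult(vip=s, important=s > 1.0)


def loading_classes(model: OPLSModel, columns: "list[str] | None" = None) -> pd.Series:
    """Coarse three-way partition of predictive loadings.

    A reconstruction of the qualitative High I / High II / Low reading of a
    loading plot: negative predictive loadings (variables expressed at low
    %MVC) are "Low"; non-negative loadings are "High I" when their
    magnitude reaches the top tertile of all |loadings|, else "High II".
    """
    p = model.p_pred
    cut = np.quantile(np.abs(p), 2.0 / 3.0)
    labels = np.where(p < 0, "Low", np.where(np.abs(p) >= cut, "High I", "High II"))
    idx = columns if columns is not None else list(range(p.size))
    return pd.Series(labels, index=idx, name="loading_class")
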