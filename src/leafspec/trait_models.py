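"""PLSR reflectance-trait models with LooCV component selection and VIP.

Single-response partial least squares regression by the NIPALS deflation
scheme (mean-centered X and y, no variance scaling).  For one response the
algorithm is fully deterministic: each component's weight vector is the
normalised covariance X'y of the deflated data, with no inner iteration.

Model quality is assessed by leave-one-out cross-validation: the component
count is chosen at the minimum of the RMSEP curve (ties toward fewer
components, for parsimony), and performance is reported as R_CV² (squared
Pearson correlation of measured vs LooCV-predicted values) and nRMSE
(RMSEP as a percentage of the observed trait range).  Wavelength importance
uses the Variable Importance in Projection (VIP) score, whose squared
values average to 1 over bands by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLSRModel",
    "CVResult",
    "fit_plsr",
    "predict",
    "loocv_predictions",
    "loocv_rmsep",
    "select_components",
    "evaluate_cv",
    "compute_vip",
    "select_model_traits",
]

MAX_COMPONENTS_DEFAULT = 30


@dataclass
class PLSRModel:
    """Fitted single-response PLSR model.

    ``weights`` (P x A) hold the unit-norm NIPALS weight vectors,
    ``x_loadings`` (P x A) the X loadings, ``y_loadings`` (A,) the scalar
    y loadings, ``t_sq`` (A,) the score sums of squares; together these
    determine the regression coefficients at any truncation a <= A.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    t_sq: np.ndarray
    trait: str = ""

    @property
    def n_bands(self) -> int:
        return self.x_mean.size

    def coefficients(self, k: int | None = None) -> np.ndarray:
        """Regression coefficients of the centered model at k components."""
        k = self.n_components if k is None else k
        if not (1 <= k <= self.n_components):
            raise ValueError(f"k must lie in [1, {self.n_components}]")
        W = self.weights[:, :k]
        P = self.x_loadings[:, :k]
        Q = self.y_loadings[:k]
        # R = W (P'W)^-1 maps raw centered X to scores
        R = np.linalg.solve((P.T @ W).T, W.T).T
        return R @ Q

    @property
    def vip(self) -> np.ndarray:
        return compute_vip(self)


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary for one trait model."""

    trait: str
    rmsep_curve: np.ndarray
    selected_k: int
    predictions: np.ndarray
    measured: np.ndarray = field(repr=False, default=None)
    r2_cv: float = np.nan
    nrmse: float = np.nan

    @property
    def rmsep(self) -> float:
        return float(self.rmsep_curve[self.selected_k - 1])


def fit_plsr(X: np.ndarray, y: np.ndarray, k: int, trait: str = "") -> PLSRModel:
    """Fit a k-component single-response PLSR model (NIPALS).

    X is (N, P) reflectance, y (N,) the trait.  Raises if k exceeds the
    feasible component count min(N-1, P).  A zero-variance y yields a
    degenerate model that predicts the mean (all coefficients zero).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k={k} infeasible for N={n}, P={p}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((p, k))
    Pl = np.zeros((p, k))
    Q = np.zeros(k)
    Tsq = np.zeros(k)
    tol = np.finfo(float).eps * max(n, p)
    ynorm0 = np.linalg.norm(yd)
    for a in range(k):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if ynorm0 == 0 or nw <= tol * max(1.0, ynorm0):
            break  # X-y covariance exhausted; remaining components are null
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        p_a = (Xd.T @ t) / tt
        q_a = float(yd @ t) / tt
        W[:, a], Pl[:, a], Q[a], Tsq[a] = w, p_a, q_a, tt
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
    return PLSRModel(
        n_components=k,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=Pl,
        y_loadings=Q,
        t_sq=Tsq,
        trait=trait,
    )


def predict(model: PLSRModel, X: np.ndarray, k: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    active = int(np.count_nonzero(model.t_sq))
    k = model.n_components if k is None else k
    k_eff = min(k, active) if active else 0
    if k_eff == 0:
        return np.full(X.shape[0], model.y_mean)
    beta = model.coefficients(k_eff)
    return (X - model.x_mean) @ beta + model.y_mean


def _predict_all_k(model: PLSRModel, x: np.ndarray) -> np.ndarray:
    """Predictions of one sample at every component count 1..A (vector)."""
    active = int(np.count_nonzero(model.t_sq))
    out = np.full(model.n_components, model.y_mean)
    xd = x - model.x_mean
    acc = model.y_mean
    for a in range(active):
        t_a = float(xd @ model.weights[:, a])
        acc += model.y_loadings[a] * t_a
        xd = xd - t_a * model.x_loadings[:, a]
        out[a] = acc
    if active:
        out[active:] = out[active - 1]
    return out


def loocv_predictions(X: np.ndarray, y: np.ndarray, max_k: int = MAX_COMPONENTS_DEFAULT) -> np.ndarray:
    """(N, K) matrix of LooCV predictions for component counts 1..K.

    K = min(max_k, N-2, P); each row i is predicted by a model refitted
    without sample i.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 4:
        raise ValueError("LooCV needs at least 4 samples")
    k = min(max_k, n - 2, p)
    preds = np.empty((n, k))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = fit_plsr(X[keep], y[keep], k)
        preds[i] = _predict_all_k(model, X[i])
    return preds


def loocv_rmsep(X: np.ndarray, y: np.ndarray, max_k: int = MAX_COMPONENTS_DEFAULT) -> np.ndarray:
    """RMSEP per component count 1..min(max_k, feasible)."""
    preds = loocv_predictions(X, y, max_k)
    resid = preds - np.asarray(y, dtype=float)[:, None]
    return np.sqrt(np.mean(resid**2, axis=0))


def select_components(rmsep_curve: np.ndarray) -> int:
    """Component count at the RMSEP minimum; ties go to fewer components."""
    curve = np.asarray(rmsep_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSEP curve")
    return int(np.argmin(curve)) + 1


def evaluate_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int | None = None,
    max_k: int = MAX_COMPONENTS_DEFAULT,
    trait: str = "",
) -> CVResult:
    """LooCV diagnostics: RMSEP curve, selected k, R_CV² and nRMSE (%)."""
    y = np.asarray(y, dtype=float).ravel()
    y_range = float(np.max(y) - np.min(y))
    if y_range == 0:
        raise ValueError("zero trait range: nRMSE undefined")
    preds = loocv_predictions(X, y, max_k)
    curve = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    selected = select_components(curve) if k is None else int(k)
    if not (1 <= selected <= curve.size):
        raise ValueError(f"k={selected} outside the evaluated range")
    yhat = preds[:, selected - 1]
    r = np.corrcoef(y, yhat)[0, 1]
    return CVResult(
        trait=trait,
        rmsep_curve=curve,
        selected_k=selected,
        predictions=yhat,
        measured=y,
        r2_cv=float(r**2),
        nrmse=float(curve[selected - 1] / y_range * 100.0),
    )


def compute_vip(model: PLSRModel) -> np.ndarray:
    """Variable Importance in Projection per band.

    VIP_j = sqrt( P * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a ) with
    SS_a = q_a² t_a't_a the y-variance captured by component a.  The mean of
    squared VIP over bands is exactly 1.
    """
    active = int(np.count_nonzero(model.t_sq))
    if active == 0:
        raise ValueError("degenerate model: no fitted components")
    ss = (model.y_loadings[:active] ** 2) * model.t_sq[:active]
    w = model.weights[:, :active]  # unit-norm columns
    p = model.n_bands
    return np.sqrt(p * (w**2 @ ss) / ss.sum())


def select_model_traits(
    ndsi_maps: dict,
    trait_table: pd.DataFrame,
    r2_threshold: float = 0.15,
    alpha: float = 0.01,
    corr_threshold: float = 0.5,
) -> list[str]:
    """Traits worth a PLSR model: spectrally sensitive and mutually distinct.

    A trait is a candidate when its best Bonferroni-significant NDSI pair
    scores R_cal² > ``r2_threshold``.  Candidates are then pruned greedily
    in decreasing order of that score: a trait is dropped when it correlates
    with an already-kept trait at |r| > ``corr_threshold`` (the
    higher-scoring trait of the pair survives).
    """
    from .spectral_indices import best_band_pair

    best = {}
    for trait, ndsi_map in ndsi_maps.items():
        hit = best_band_pair(ndsi_map, alpha=alpha)
        if hit is not None and hit[1] > r2_threshold:
            best[trait] = hit[1]
    ranked = sorted(best, key=lambda t: (-best[t], t))
    kept: list[str] = []
    for trait in ranked:
        ok = True
        for other in kept:
            r = trait_table[trait].corr(trait_table[other])
            if np.isfinite(r) and abs(r) > corr_threshold:
                ok = False
                break
        if ok:
            kept.append(trait)
    return kept
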