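"""Sparse partial least squares discriminant analysis, written from scratch.

sPLS-DA regresses a dummy-coded two-class response on a high-dimensional
feature matrix through a small number of latent components, sparsifying each
X-weight vector so that exactly ``keepX`` features carry nonzero loadings per
component. The algorithm follows the classical sparse-PLS formulation:

1. Center X and unit-variance scale its columns; dummy-code y into one
   indicator column per class and center/scale those too.
2. Per component h: form the cross-covariance M = X_h' Y_h; alternate
   u <- soft_threshold(M v, keepX), v <- M'u (both renormalized) until
   convergence. Soft thresholding keeps the keepX largest |entries| and
   shrinks them by the (keepX+1)-th magnitude.
3. Form the score t = X_h u, regression loadings c = X_h't / t't and
   d = Y_h't / t't, and deflate both matrices (regression mode):
   X_{h+1} = X_h - t c', Y_{h+1} = Y_h - t d'.

Prediction projects new (identically scaled) data through W(P'W)^{-1} onto
the latent space, reconstructs the dummy response, and assigns classes by a
configurable distance (max_dist by default). The continuous risk score is
the predicted positive-class indicator minus the negative one; it is
positive exactly when max_dist would call the positive class.

Fitting and prediction are fully deterministic; the only randomness in the
module is the fold split of :func:`tune_splsda`, driven by its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import MappingError, ParameterError

PREDICTION_DISTANCES = ("max_dist", "centroid_dist", "mahalanobis_dist")


def _soft_threshold(u: np.ndarray, keep: int, mode: str = "soft") -> np.ndarray:
    """Keep the ``keep`` largest |entries| of u; soft mode shrinks them.

    Shrinkage subtracts the (keep+1)-th largest magnitude from the survivors
    (the classic sparse-PLS penalty); ``hard`` keeps raw values. Ties beyond
    position ``keep`` are broken by index order.
    """
    p = len(u)
    if keep >= p:
        return u.copy()
    mag = np.abs(u)
    # stable top-k: sort by (-|u|, index)
    order = np.lexsort((np.arange(p), -mag))
    kept = order[:keep]
    lam = mag[order[keep]]
    out = np.zeros_like(u)
    if mode == "soft":
        out[kept] = np.sign(u[kept]) * np.maximum(mag[kept] - lam, 0.0)
        if not np.any(out):  # fully tied block: fall back to hard selection
            out[kept] = u[kept]
    else:
        out[kept] = u[kept]
    return out


@dataclass
class SplsdaModel:
    """A fitted sparse PLS-DA model (everything needed for prediction)."""

    feature_names: list[str]
    classes: list[str]  # column order of the dummy response [negative, positive]
    positive_class: str
    ncomp: int
    keepX: list[int]
    x_weights: np.ndarray  # p x H, sparse, unit norm
    x_loadings: np.ndarray  # p x H regression loadings
    y_loadings: np.ndarray  # q x H
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    scores: np.ndarray  # n x H training latent scores
    train_labels: list[str]
    x_mean_balanced: np.ndarray | None = None  # average of per-class feature means
    prediction_distance: str = "max_dist"
    sparsity_mode: str = "soft"

    @property
    def selected_features(self) -> list[str]:
        """Union of features with a nonzero loading on any component."""
        nz = np.any(self.x_weights != 0.0, axis=1)
        return [f for f, keep in zip(self.feature_names, nz) if keep]

    def selected_per_component(self) -> list[list[str]]:
        return [
            [f for f, w in zip(self.feature_names, self.x_weights[:, h]) if w != 0.0]
            for h in range(self.ncomp)
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "classes": self.classes,
            "positive_class": self.positive_class,
            "ncomp": self.ncomp,
            "keepX": self.keepX,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_scale": self.y_scale.tolist(),
            "scores": self.scores.tolist(),
            "train_labels": self.train_labels,
            "x_mean_balanced": None if self.x_mean_balanced is None
            else self.x_mean_balanced.tolist(),
            "prediction_distance": self.prediction_distance,
            "sparsity_mode": self.sparsity_mode,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplsdaModel":
        d = json.loads(Path(path).read_text())
        for k in ("x_weights", "x_loadings", "y_loadings", "x_mean",
                  "x_scale", "y_mean", "y_scale", "scores"):
            d[k] = np.asarray(d[k], dtype=float)
        if d.get("x_mean_balanced") is not None:
            d["x_mean_balanced"] = np.asarray(d["x_mean_balanced"], dtype=float)
        return cls(**d)


def _dummy_code(y: Sequence[str], positive_class: str | None) -> tuple[np.ndarray, list[str], str]:
    labels = pd.Series(list(y), dtype=str)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ParameterError(f"exactly two classes required, got {classes}")
    if positive_class is None:
        for cand in ("high", "case"):
            if cand in classes:
                positive_class = cand
                break
        else:
            # default: the minority class (ties -> last in sorted order)
            counts = labels.value_counts()
            positive_class = sorted(classes, key=lambda c: (counts[c], c))[0] \
                if counts[classes[0]] != counts[classes[1]] else classes[1]
    if positive_class not in classes:
        raise ParameterError(f"positive_class {positive_class!r} not among {classes}")
    negative_class = next(c for c in classes if c != positive_class)
    ordered = [negative_class, positive_class]
    Y = np.column_stack([(labels == c).to_numpy(float) for c in ordered])
    return Y, ordered, positive_class


def fit_splsda(
    X: pd.DataFrame,
    y: Sequence[str],
    ncomp: int = 3,
    keepX: int | Sequence[int] | None = None,
    positive_class: str | None = None,
    scale: bool = True,
    prediction_distance: str = "max_dist",
    sparsity_mode: str = "soft",
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SplsdaModel:
    """Fit a two-class sparse PLS-DA model.

    Parameters
    ----------
    X
        Samples x features DataFrame of log-normalized expression.
    y
        Class label per sample (exactly two distinct labels).
    ncomp
        Number of latent components.
    keepX
        Retained features per component (int, or one value per component;
        ``None`` keeps everything, i.e. dense PLS-DA). Values are clamped to
        the number of usable features.
    positive_class
        Label treated as the positive (case / high-risk) class. Defaults to
        ``"high"`` or ``"case"`` when present, else the minority class.
    """
    if prediction_distance not in PREDICTION_DISTANCES:
        raise ParameterError(f"unknown prediction distance {prediction_distance!r}")
    if sparsity_mode not in ("soft", "hard"):
        raise ParameterError(f"unknown sparsity mode {sparsity_mode!r}")
    X = pd.DataFrame(X)
    n, p_all = X.shape
    if n < 4:
        raise ParameterError("at least 4 samples are required")
    if len(y) != n:
        raise ParameterError("y length must match the number of rows of X")
    if ncomp < 1:
        raise ParameterError("ncomp must be >= 1")

    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0, ddof=1)
    constant = sd == 0.0
    if constant.any():
        dropped = [f for f, c in zip(X.columns, constant) if c]
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}")
        X = X.loc[:, ~constant]
        Xv = X.to_numpy(dtype=float)
        sd = sd[~constant]
    features = [str(c) for c in X.columns]
    p = len(features)
    if p == 0:
        raise ParameterError("no non-constant features to fit on")
    ncomp = min(ncomp, p, n - 1)

    if keepX is None:
        keep = [p] * ncomp
    elif np.isscalar(keepX):
        keep = [int(keepX)] * ncomp
    else:
        keep = [int(k) for k in keepX]
        if len(keep) < ncomp:
            raise ParameterError("keepX must provide one value per component")
        keep = keep[:ncomp]
    if any(k < 1 for k in keep):
        raise ParameterError("keepX values must be >= 1")
    keep = [min(k, p) for k in keep]

    Y, classes, positive_class = _dummy_code(y, positive_class)
    x_mean = Xv.mean(axis=0)
    x_scale = sd if scale else np.ones(p)
    Xs = (Xv - x_mean) / x_scale
    y_mean = Y.mean(axis=0)
    y_sd = Y.std(axis=0, ddof=1)
    y_scale = y_sd if scale else np.ones(Y.shape[1])
    Ys = (Y - y_mean) / y_scale

    H = ncomp
    W = np.zeros((p, H))
    P = np.zeros((p, H))
    D = np.zeros((Y.shape[1], H))
    T = np.zeros((n, H))
    Xh, Yh = Xs.copy(), Ys.copy()
    for h in range(H):
        M = Xh.T @ Yh  # p x q cross-covariance
        # initialize v from the leading eigenvector of M'M (q x q, q = 2)
        evals, evecs = np.linalg.eigh(M.T @ M)
        v = evecs[:, -1]
        u = np.zeros(p)
        for _ in range(max_iter):
            u_new = _soft_threshold(M @ v, keep[h], sparsity_mode)
            nrm = np.linalg.norm(u_new)
            if nrm == 0.0:
                break
            u_new /= nrm
            v = M.T @ u_new
            vn = np.linalg.norm(v)
            if vn > 0:
                v /= vn
            if np.linalg.norm(u_new - u) < tol:
                u = u_new
                break
            u = u_new
        t = Xh @ u
        tt = float(t @ t)
        if tt <= 0:
            raise ParameterError(f"degenerate component {h + 1}: zero-variance score")
        c = Xh.T @ t / tt
        d = Yh.T @ t / tt
        Xh = Xh - np.outer(t, c)
        Yh = Yh - np.outer(t, d)
        W[:, h], P[:, h], D[:, h], T[:, h] = u, c, d, t

    labels_arr = np.asarray([str(v) for v in y])
    x_mean_balanced = np.mean(
        [Xv[labels_arr == c].mean(axis=0) for c in classes], axis=0
    )
    return SplsdaModel(
        feature_names=features,
        classes=classes,
        positive_class=positive_class,
        ncomp=H,
        keepX=keep,
        x_weights=W,
        x_loadings=P,
        y_loadings=D,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        scores=T,
        train_labels=labels_arr.tolist(),
        x_mean_balanced=x_mean_balanced,
        prediction_distance=prediction_distance,
        sparsity_mode=sparsity_mode,
    )


def _project(model: SplsdaModel, Xnew: pd.DataFrame) -> np.ndarray:
    """Scale new data with training statistics and project to latent scores."""
    Xnew = pd.DataFrame(Xnew)
    missing = [f for f in model.feature_names if f not in Xnew.columns]
    if missing:
        raise MappingError(
            f"new data is missing {len(missing)} model feature(s): {missing[:5]}"
        )
    Xv = Xnew[model.feature_names].to_numpy(dtype=float)
    Xs = (Xv - model.x_mean) / model.x_scale
    W, P = model.x_weights, model.x_loadings
    Wstar = W @ np.linalg.inv(P.T @ W)
    return Xs @ Wstar


def predict_splsda(
    model: SplsdaModel, Xnew: pd.DataFrame, distance: str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Predicted dummy outcomes (one column per class) and class labels.

    The dummy predictions are on the original indicator scale, so a value
    near 1 in a class column means "looks like that class". Labels follow
    the model's prediction distance unless overridden.
    """
    distance = distance or model.prediction_distance
    if distance not in PREDICTION_DISTANCES:
        raise ParameterError(f"unknown prediction distance {distance!r}")
    Xnew = pd.DataFrame(Xnew)
    scores = _project(model, Xnew)
    Ys_hat = scores @ model.y_loadings.T
    Y_hat = Ys_hat * model.y_scale + model.y_mean
    ypred = pd.DataFrame(Y_hat, index=Xnew.index, columns=model.classes)

    if distance == "max_dist":
        labels = ypred.idxmax(axis=1)
    else:
        train = model.scores
        lab = np.asarray(model.train_labels)
        cents = np.stack([train[lab == c].mean(axis=0) for c in model.classes])
        if distance == "centroid_dist":
            d2 = ((scores[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        else:  # mahalanobis_dist: pooled within-class covariance of scores
            resid = train - cents[[model.classes.index(c) for c in lab]]
            cov = np.atleast_2d(np.cov(resid, rowvar=False, ddof=len(model.classes)))
            cov_inv = np.linalg.pinv(cov)
            diff = scores[:, None, :] - cents[None, :, :]
            d2 = np.einsum("nkp,pq,nkq->nk", diff, cov_inv, diff)
        labels = pd.Series(
            [model.classes[j] for j in d2.argmin(axis=1)], index=Xnew.index
        )
    return ypred, pd.Series(labels, index=Xnew.index, name="predicted")


def risk_score(model: SplsdaModel, Xnew: pd.DataFrame) -> pd.Series:
    """Continuous risk score: predicted positive dummy minus negative dummy.

    Higher is more case-like; under max_dist the label is positive exactly
    when the score exceeds zero.
    """
    ypred, _ = predict_splsda(model, Xnew)
    neg, pos = model.classes[0], model.classes[1]
    score = ypred[pos] - ypred[neg]
    score.name = "risk_score"
    return score


@dataclass
class TuningResult:
    """10-fold CV grid search over (ncomp, keepX) candidates."""

    grid: pd.DataFrame  # columns ncomp, keepX, cv_error
    best_ncomp: int
    best_keepX: int
    best_error: float
    folds: int
    seed: int


def tune_splsda(
    X: pd.DataFrame,
    y: Sequence[str],
    keepX_grid: Sequence[int] = (5, 10, 15, 20, 25),
    ncomp_grid: Sequence[int] = (3,),
    folds: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> TuningResult:
    """Choose (ncomp, keepX) by stratified k-fold CV misclassification.

    The CV error of a candidate is the mean fold misclassification rate;
    ties break toward the sparser model (fewer components, then smaller
    keepX). Fold assignment is stratified and reproducible from ``seed``.
    """
    X = pd.DataFrame(X)
    y = pd.Series(list(y), dtype=str).to_numpy()
    n = len(y)
    if not len(keepX_grid) or not len(ncomp_grid):
        raise ParameterError("tuning grid must be nonempty")
    if folds > n:
        raise ParameterError("folds cannot exceed the number of samples")
    counts = pd.Series(y).value_counts()
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise ParameterError(
            "cannot stratify: the smaller class needs at least 2 samples"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(n), y))
    for train_idx, _ in splits:
        if len(set(y[train_idx])) < 2:
            raise ParameterError("a training fold contains a single class")

    rows = []
    for ncomp, keep in product(ncomp_grid, keepX_grid):
        errs = []
        for train_idx, test_idx in splits:
            model = fit_splsda(
                X.iloc[train_idx], y[train_idx], ncomp=ncomp, keepX=keep, **fit_kwargs
            )
            _, pred = predict_splsda(model, X.iloc[test_idx])
            errs.append(float(np.mean(pred.to_numpy() != y[test_idx])))
        rows.append({"ncomp": ncomp, "keepX": keep, "cv_error": float(np.mean(errs))})
    grid = pd.DataFrame(rows)
    best = grid.sort_values(["cv_error", "ncomp", "keepX"]).iloc[0]
    return TuningResult(
        grid=grid,
        best_ncomp=int(best["ncomp"]),
        best_keepX=int(best["keepX"]),
        best_error=float(best["cv_error"]),
        folds=folds,
        seed=seed,
    )
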