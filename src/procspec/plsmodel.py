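"""NIPALS PLS1 regression and the validation schemes used for moisture calibration.

The calibration target is a single response (LOD moisture %), so the model is
PLS1: the NIPALS sequence of weight/score/loading extraction with X-deflation
per latent variable. Data are mean-centered, never autoscaled — the spectra
share units, and variance scaling of spectral channels is nonstandard.

Validation follows process-chemometrics practice: leave-one-sample-out CV,
leave-a-batch-out CV (folds are whole batches, the conservative scheme for
batch processes), and external validation on a preselected batch subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone

from .dataset import PairedData

__all__ = [
    "NIPALSPLS",
    "ValidationReport",
    "fit_pls",
    "rmse",
    "r2",
    "loo_cv",
    "lbo_cv",
    "validate_external",
    "lv_scan",
]


def rmse(y, y_hat) -> float:
    """Root-mean-square error, in the units of y (moisture %)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r2(y, y_hat) -> float:
    """Coefficient of determination; SS_tot about the mean of the evaluated set."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    ss_res = np.sum((y - y_hat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined: zero variance in y")
    return float(1.0 - ss_res / ss_tot)


class NIPALSPLS(BaseEstimator, RegressorMixin):
    """PLS1 regression via NIPALS with X-deflation.

    Parameters
    ----------
    n_components : int
        Number of latent variables A.
    tol, max_iter :
        Inner-loop convergence control. For a single response the weight
        vector is obtained in one pass analytically; the loop is kept for
        robustness and exits immediately in practice.

    Attributes
    ----------
    x_mean_, y_mean_ : training means used for centering.
    x_weights_ : ndarray (p, A) — weight vectors w_a (unit norm).
    x_loadings_ : ndarray (p, A) — loadings p_a.
    y_loadings_ : ndarray (A,) — regression loadings q_a.
    x_scores_ : ndarray (n, A) — training scores t_a (mutually orthogonal).
    coef_ : ndarray (p,) — regression vector for centered data at A components.
    """

    def __init__(self, n_components: int = 7, tol: float = 1e-10, max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
        A = int(self.n_components)
        if A < 1:
            raise ValueError("n_components must be >= 1")
        if X.shape[0] < A + 1:
            raise ValueError(f"need at least n_components+1={A + 1} samples, got {X.shape[0]}")
        if np.ptp(y) == 0:
            raise ValueError("degenerate y: zero variance")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        E = X - self.x_mean_
        f = y - self.y_mean_

        n, p = E.shape
        W = np.zeros((p, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        T = np.zeros((n, A))
        for a in range(A):
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw < 1e-12 * max(1.0, np.linalg.norm(E)):
                raise ValueError(
                    f"n_components={A} exceeds the effective rank of X "
                    f"(residual exhausted at component {a + 1})"
                )
            w /= nw
            for _ in range(self.max_iter):
                t = E @ w
                w_new = E.T @ f
                w_new /= np.linalg.norm(w_new)
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w = w_new
            t = E @ w
            tt = t @ t
            if tt < 1e-24:
                raise ValueError(
                    f"n_components={A} exceeds the effective rank of X "
                    f"(zero score at component {a + 1})"
                )
            pa = E.T @ t / tt
            qa = f @ t / tt
            E = E - np.outer(t, pa)
            f = f - qa * t
            W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = T
        self.n_features_in_ = p
        self.coef_ = self.coefficients()
        return self

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector B_a = W_a (P_a' W_a)^{-1} q_a for centered data.

        ``n_components`` may be any value up to the fitted A, which lets a
        single fit serve a whole latent-variable scan.
        """
        A = self.x_weights_.shape[1] if n_components is None else int(n_components)
        if not 1 <= A <= self.x_weights_.shape[1]:
            raise ValueError(f"n_components must be in [1, {self.x_weights_.shape[1]}]")
        W = self.x_weights_[:, :A]
        P = self.x_loadings_[:, :A]
        q = self.y_loadings_[:A]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.x_mean_.size:
            raise ValueError(
                f"wavelength grid mismatch: model has {self.x_mean_.size} channels, "
                f"input has shape {X.shape}"
            )
        coef = self.coef_ if n_components is None else self.coefficients(n_components)
        return self.y_mean_ + (X - self.x_mean_) @ coef


def fit_pls(X, y, n_components: int = 7) -> NIPALSPLS:
    """Thin functional wrapper: fit a NIPALS PLS1 model."""
    return NIPALSPLS(n_components=n_components).fit(X, y)


@dataclass
class ValidationReport:
    """Accuracy summary of one validation scheme.

    ``predictions`` holds one row per evaluated sample:
    batch_id, sample_time_s, lod_percent, predicted.
    """

    scheme: str
    rmse: float
    r2: float
    predictions: pd.DataFrame = field(repr=False)

    def summary(self) -> dict:
        return {"scheme": self.scheme, "rmse": self.rmse, "r2": self.r2,
                "n": int(len(self.predictions))}


def _apply_chain(chain, X_train, X_eval):
    """Fit sample-wise transformers on the training fold, apply to both."""
    if not chain:
        return X_train, X_eval
    for step in chain:
        step = clone(step)
        X_train = step.fit_transform(X_train)
        X_eval = step.transform(X_eval)
    return X_train, X_eval


def _report(scheme: str, paired: PairedData, y_hat: np.ndarray) -> ValidationReport:
    df = pd.DataFrame(
        {
            "batch_id": paired.batch_ids,
            "sample_time_s": paired.sample_times,
            "lod_percent": paired.lod,
            "predicted": y_hat,
        }
    )
    return ValidationReport(scheme=scheme, rmse=rmse(paired.lod, y_hat),
                            r2=r2(paired.lod, y_hat), predictions=df)


def calibration_fit(paired: PairedData, n_components: int = 7, chain=None):
    """Fit on all rows; return (model, fitted chain steps, calibration report)."""
    X = paired.spectra
    fitted = []
    for step in chain or []:
        step = clone(step)
        X = step.fit_transform(X)
        fitted.append(step)
    model = NIPALSPLS(n_components=n_components).fit(X, paired.lod)
    y_hat = model.predict(X)
    return model, fitted, _report("calibration", paired, y_hat)


def loo_cv(paired: PairedData, n_components: int = 7, chain=None) -> ValidationReport:
    """Leave-one-sample-out (full) cross-validation.

    Transformers that learn parameters (the MSC reference) are re-fit inside
    each fold; time smoothing belongs to the batch stream before pairing and
    is therefore not part of ``chain``.
    """
    n = paired.n_samples
    if n < n_components + 2:
        raise ValueError(f"need at least n_components+2={n_components + 2} samples, got {n}")
    y_hat = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train, test = paired.subset(mask), paired.subset(~mask)
        X_tr, X_te = _apply_chain(chain, train.spectra, test.spectra)
        model = NIPALSPLS(n_components=n_components).fit(X_tr, train.lod)
        y_hat[i] = model.predict(X_te)[0]
    return _report("LOO CV", paired, y_hat)


def lbo_cv(paired: PairedData, n_components: int = 7, chain=None) -> ValidationReport:
    """Leave-a-batch-out cross-validation: folds are whole batches."""
    batches = pd.unique(paired.batch_ids)
    if len(batches) < 2:
        raise ValueError("leave-a-batch-out CV needs at least 2 batches")
    y_hat = np.empty(paired.n_samples)
    for bid in batches:
        held = paired.batch_ids == bid
        train, test = paired.subset(~held), paired.subset(held)
        X_tr, X_te = _apply_chain(chain, train.spectra, test.spectra)
        model = NIPALSPLS(n_components=n_components).fit(X_tr, train.lod)
        y_hat[held] = model.predict(X_te)
    return _report("LBO CV", paired, y_hat)


def validate_external(
    calibration: PairedData,
    validation: PairedData,
    n_components: int = 7,
    chain=None,
) -> tuple[NIPALSPLS, ValidationReport]:
    """Fit on the calibration batches, predict the preselected validation set."""
    overlap = set(calibration.batch_ids) & set(validation.batch_ids)
    if overlap:
        raise ValueError(f"calibration and validation share batch(es): {sorted(overlap)}")
    X_tr, X_va = _apply_chain(chain, calibration.spectra, validation.spectra)
    model = NIPALSPLS(n_components=n_components).fit(X_tr, calibration.lod)
    y_hat = model.predict(X_va)
    return model, _report("external", validation, y_hat)


def lv_scan(
    paired: PairedData,
    a_max: int,
    scheme: str = "lbo",
    chain=None,
    validation: PairedData | None = None,
) -> pd.DataFrame:
    """RMSE as a function of the number of latent variables, 1..a_max.

    Each fold is fit once at ``a_max`` components; predictions for smaller A
    reuse the same decomposition. Schemes: ``calibration``, ``loo``, ``lbo``,
    ``external`` (requires ``validation``).
    """
    if a_max < 1:
        raise ValueError("a_max must be >= 1")

    def fold_predict(train: PairedData, test: PairedData) -> np.ndarray:
        X_tr, X_te = _apply_chain(chain, train.spectra, test.spectra)
        model = NIPALSPLS(n_components=a_max).fit(X_tr, train.lod)
        return np.column_stack(
            [model.predict(X_te, n_components=a) for a in range(1, a_max + 1)]
        )

    n = paired.n_samples
    if scheme == "calibration":
        preds = fold_predict(paired, paired)
        y = paired.lod
    elif scheme == "loo":
        preds = np.empty((n, a_max))
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            preds[i] = fold_predict(paired.subset(mask), paired.subset(~mask))[0]
        y = paired.lod
    elif scheme == "lbo":
        preds = np.empty((n, a_max))
        for bid in pd.unique(paired.batch_ids):
            held = paired.batch_ids == bid
            preds[held] = fold_predict(paired.subset(~held), paired.subset(held))
        y = paired.lod
    elif scheme == "external":
        if validation is None:
            raise ValueError("scheme='external' requires a validation set")
        preds = fold_predict(paired, validation)
        y = validation.lod
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    return pd.DataFrame(
        {"n_components": np.arange(1, a_max + 1),
         "rmse": [rmse(y, preds[:, a - 1]) for a in range(1, a_max + 1)]}
    )
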