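"""Partial least squares learners.

Two flavours are needed.  :func:`fit_pls_cox` builds survival-predictive
components from one omics block: each component direction is assembled from
per-feature Cox scores (the coefficient of the feature in a proportional-
hazards fit adjusted for the components already extracted), the component is
the corresponding linear combination of standardized features, and the
block is deflated before the next round.  :func:`fit_pls_linear` is
classical orthogonal-scores (NIPALS) PLS regression with a multivariate
response, used to re-express one block's components in another block's
features.

Both learners store everything needed to make their predictions affine in
the raw input features, which is what lets the whole pipeline be composed
into a single feature-level weight matrix downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil, log10

import numpy as np
import pandas as pd

from .omics import SurvivalOutcome
from .survival import CoxEngine, CoxModel, _newton, fit_cox, predict_lp

logger = logging.getLogger("plasma_surv")


def default_n_components(n_features: int) -> int:
    """Number of PLS components for a block of ``n_features`` features:
    ``max(2, ceil(log10(n_features)))``.

    Grows logarithmically with block width, so narrow clinical tables get 2
    components while genome-wide blocks of a few thousand features get 4.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return max(2, ceil(log10(n_features)))


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)  # constant features -> zero column
    return mean, scale


# ---------------------------------------------------------------------------
# PLS linear regression (multi-response, orthogonal scores)


@dataclass
class PlsLinearModel:
    """Orthogonal-scores PLS regression of a multivariate response on
    centered, unit-scaled features.

    Prediction is affine in the raw features:
    ``Yhat = (X - x_mean) / x_scale @ B + y_mean``.
    """

    feature_names: list[str]
    response_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # (p, K) unit-norm feature weights
    x_loadings: np.ndarray  # (p, K)
    y_loadings: np.ndarray  # (m, K)
    n_components: int

    @property
    def B(self) -> np.ndarray:
        """(p, m) coefficient matrix on the standardized feature scale."""
        W, P, Q = self.weights, self.x_loadings, self.y_loadings
        if self.n_components == 0:
            return np.zeros((len(self.feature_names), len(self.response_names)))
        wstar = W @ np.linalg.inv(P.T @ W)
        return wstar @ Q.T

    def affine(self) -> tuple[np.ndarray, np.ndarray]:
        """(coefficients, intercept) of the prediction map on the *raw*
        feature scale: ``Yhat = X @ coefs + intercept``."""
        coefs = self.B / self.x_scale[:, None]
        intercept = self.y_mean - (self.x_mean / self.x_scale) @ self.B
        return coefs, intercept

    def predict(self, X) -> pd.DataFrame | np.ndarray:
        return predict_pls_linear(self, X)

    def to_dict(self) -> dict:
        return {
            "kind": "pls_linear",
            "feature_names": list(self.feature_names),
            "response_names": list(self.response_names),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsLinearModel":
        d = {k: v for k, v in d.items() if k != "kind"}
        for k in ("x_mean", "x_scale", "y_mean", "weights", "x_loadings",
                  "y_loadings"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _coerce_xy(X, Y):
    if isinstance(X, pd.DataFrame):
        fnames = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        fnames = [f"x{i}" for i in range(Xv.shape[1])]
    if isinstance(Y, (pd.DataFrame, pd.Series)):
        Yf = pd.DataFrame(Y)
        rnames = [str(c) for c in Yf.columns]
        Yv = Yf.to_numpy(dtype=float)
    else:
        Yv = np.asarray(Y, dtype=float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        rnames = [f"y{i}" for i in range(Yv.shape[1])]
    return Xv, fnames, Yv, rnames


def fit_pls_linear(X, Y, n_components: int) -> PlsLinearModel:
    """Fit orthogonal-scores PLS with a (possibly multivariate) response.

    X is centered and scaled to unit variance (constant features get weight
    zero), Y is centered.  ``n_components`` above the rank bound
    ``min(n_samples - 1, n_features)`` is clipped with a warning; extraction
    also stops early if the remaining covariance is numerically zero.
    """
    Xv, fnames, Yv, rnames = _coerce_xy(X, Y)
    n, p = Xv.shape
    if Yv.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if not (np.isfinite(Xv).all() and np.isfinite(Yv).all()):
        raise ValueError("missing values in PLS inputs; impute upstream")
    bound = max(1, min(n - 1, p))
    K = int(n_components)
    if K < 1:
        raise ValueError("n_components must be >= 1")
    if K > bound:
        warnings.warn(
            f"n_components={K} exceeds the rank bound {bound}; clipped",
            stacklevel=2,
        )
        K = bound

    x_mean, x_scale = _standardize_fit(Xv)
    Xh = (Xv - x_mean) / x_scale
    y_mean = Yv.mean(axis=0)
    Yh = Yv - y_mean

    W = np.zeros((p, K))
    P = np.zeros((p, K))
    Q = np.zeros((Yv.shape[1], K))
    k_used = 0
    for h in range(K):
        C = Xh.T @ Yh  # p x m covariance
        if np.linalg.norm(C) < 1e-12:
            break
        if C.shape[1] == 1:
            w = C[:, 0]
        else:
            # dominant left singular vector of the covariance
            u, s, vt = np.linalg.svd(C, full_matrices=False)
            w = u[:, 0]
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        # deterministic sign: largest-magnitude entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xh @ w
        tt = t @ t
        if tt < 1e-12:
            break
        W[:, h] = w
        P[:, h] = Xh.T @ t / tt
        Q[:, h] = Yh.T @ t / tt
        Xh = Xh - np.outer(t, P[:, h])
        Yh = Yh - np.outer(t, Q[:, h])
        k_used += 1
    if k_used < K:
        logger.info("fit_pls_linear: covariance exhausted after %d of %d "
                    "components", k_used, K)
    return PlsLinearModel(
        feature_names=fnames,
        response_names=rnames,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W[:, :k_used],
        x_loadings=P[:, :k_used],
        y_loadings=Q[:, :k_used],
        n_components=k_used,
    )


def predict_pls_linear(model: PlsLinearModel, X) -> pd.DataFrame | np.ndarray:
    """Apply the stored centering/scaling and affine map to new samples."""
    as_frame = isinstance(X, pd.DataFrame)
    if as_frame:
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"features missing from input: {missing[:5]}")
        Xv = X[model.feature_names].to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {Xv.shape[1]}"
            )
    if not np.isfinite(Xv).all():
        raise ValueError("missing feature values; impute upstream")
    coefs, intercept = model.affine()
    Yhat = Xv @ coefs + intercept
    if as_frame:
        return pd.DataFrame(Yhat, index=X.index, columns=model.response_names)
    return Yhat


@dataclass
class AffineComponentMap:
    """An exact affine map from one block's raw features to component
    scores: ``Y = (X - x_mean) / x_scale @ B + y_mean``.

    Used for a block's *own* components, which are by construction an exact
    linear function of its standardized features; shares the prediction
    interface of :class:`PlsLinearModel`.
    """

    feature_names: list[str]
    response_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    B: np.ndarray  # (p, m) on the standardized feature scale

    def affine(self) -> tuple[np.ndarray, np.ndarray]:
        coefs = self.B / self.x_scale[:, None]
        intercept = self.y_mean - (self.x_mean / self.x_scale) @ self.B
        return coefs, intercept

    def predict(self, X) -> pd.DataFrame | np.ndarray:
        return predict_pls_linear(self, X)

    def to_dict(self) -> dict:
        return {
            "kind": "affine",
            "feature_names": list(self.feature_names),
            "response_names": list(self.response_names),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean.tolist(),
            "B": self.B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineComponentMap":
        d = {k: v for k, v in d.items() if k != "kind"}
        for k in ("x_mean", "x_scale", "y_mean", "B"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def load_component_model(d: dict):
    """Deserialize either extension-model kind from its dict form."""
    kind = d.get("kind")
    if kind == "pls_linear":
        return PlsLinearModel.from_dict(d)
    if kind == "affine":
        return AffineComponentMap.from_dict(d)
    raise ValueError(f"unknown component model kind {kind!r}")


# ---------------------------------------------------------------------------
# PLS Cox regression


@dataclass
class PlsCoxModel:
    """Survival-predictive components for one omics block.

    ``wstar`` maps standardized features to the K component scores, so the
    whole risk prediction is affine in the raw features.  On top of the
    component-level Cox model (``cox``) two convenience models are kept:
    ``risk_model``, a proportional-hazards fit with the continuous predicted
    risk as its single predictor, and ``split_model``, the same with the
    risk dichotomized at the training median (``cutpoint``).
    """

    feature_names: list[str]
    component_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    wstar: np.ndarray  # (p, K): standardized features -> component scores
    cox: CoxModel  # Cox model on the K components
    risk_model: CoxModel
    split_model: CoxModel
    cutpoint: float
    n_components: int

    def predict_components(self, X) -> pd.DataFrame | np.ndarray:
        as_frame = isinstance(X, pd.DataFrame)
        if as_frame:
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"features missing from input: {missing[:5]}")
            Xv = X[self.feature_names].to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
        if not np.isfinite(Xv).all():
            raise ValueError("missing feature values; impute upstream")
        T = ((Xv - self.x_mean) / self.x_scale) @ self.wstar
        if as_frame:
            return pd.DataFrame(T, index=X.index, columns=self.component_names)
        return T

    def to_dict(self) -> dict:
        return {
            "kind": "pls_cox",
            "feature_names": list(self.feature_names),
            "component_names": list(self.component_names),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "wstar": self.wstar.tolist(),
            "cox": self.cox.to_dict(),
            "risk_model": self.risk_model.to_dict(),
            "split_model": self.split_model.to_dict(),
            "cutpoint": self.cutpoint,
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsCoxModel":
        d = {k: v for k, v in d.items() if k != "kind"}
        for k in ("x_mean", "x_scale", "wstar"):
            d[k] = np.asarray(d[k], dtype=float)
        for k in ("cox", "risk_model", "split_model"):
            d[k] = CoxModel.from_dict(d[k])
        return cls(**d)


def _cox_score_weights(engine: CoxEngine, T_prev: np.ndarray, Xh: np.ndarray):
    """Per-feature Cox coefficients adjusted for the existing components.

    For feature j, fit a proportional-hazards model on
    ``[T_1 .. T_{h-1}, x_j]`` (all free) and keep the coefficient of x_j.
    Columns with negligible variance get weight zero.
    """
    n, p = Xh.shape
    h = T_prev.shape[1]
    w = np.zeros(p)
    sd = Xh.std(axis=0)
    base = np.empty((n, h + 1))
    base[:, :h] = T_prev[engine.order]
    for j in range(p):
        if sd[j] < 1e-10:
            continue
        base[:, h] = Xh[engine.order, j]
        beta, _, _, _, _ = _newton(engine, base)
        w[j] = beta[h]
    return w


def fit_pls_cox(
    X,
    outcome: SurvivalOutcome,
    n_components: int | None = None,
    component_prefix: str = "comp",
) -> PlsCoxModel:
    """Build K survival-predictive PLS components from one omics block.

    The block is standardized (center, unit variance; constant features get
    weight zero).  For h = 1..K the component direction is the vector of
    per-feature Cox coefficients adjusted for the h-1 components already
    extracted, normalized to unit length; the component is the corresponding
    score, and the block is deflated by regression on it.  A final Cox model
    on the K components yields the continuous risk; the risk model, split
    model and the training-median cutpoint are fitted from the training
    risks.
    """
    if isinstance(X, pd.DataFrame):
        fnames = [str(c) for c in X.columns]
        if not X.index.equals(outcome.samples):
            X = X.reindex(outcome.samples)
        Xv = X.to_numpy(dtype=float)
        index = X.index
    else:
        Xv = np.asarray(X, dtype=float)
        fnames = [f"x{i}" for i in range(Xv.shape[1])]
        index = pd.RangeIndex(Xv.shape[0])
    n, p = Xv.shape
    if n != len(outcome):
        raise ValueError("X rows must match outcome samples")
    if not np.isfinite(Xv).all():
        raise ValueError("missing values in X; impute upstream")
    if outcome.n_events == 0:
        raise ValueError("cannot fit PLS Cox with zero events")
    if np.all(Xv.std(axis=0) == 0):
        raise ValueError("all features are constant")

    K = default_n_components(p) if n_components is None else int(n_components)
    bound = max(1, min(n - 1, p))
    if K > bound:
        warnings.warn(
            f"n_components={K} exceeds the rank bound {bound}; clipped",
            stacklevel=2,
        )
        K = bound

    x_mean, x_scale = _standardize_fit(Xv)
    Xs = (Xv - x_mean) / x_scale
    Xh = Xs.copy()
    engine = CoxEngine(outcome.time.to_numpy(), outcome.event.to_numpy())

    W = np.zeros((p, K))
    P = np.zeros((p, K))
    T = np.zeros((n, 0))
    k_used = 0
    for h in range(K):
        w = _cox_score_weights(engine, T, Xh)
        nw = np.linalg.norm(w)
        if nw < 1e-10:
            logger.info("fit_pls_cox: no remaining signal after %d component(s)", h)
            break
        w = w / nw
        t = Xh @ w
        tt = t @ t
        if tt < 1e-12:
            break
        W[:, h] = w
        P[:, h] = Xh.T @ t / tt
        Xh = Xh - np.outer(t, P[:, h])
        T = np.column_stack([T, t])
        k_used += 1
    if k_used == 0:
        raise ValueError("PLS Cox extracted no components (no survival signal?)")
    W, P = W[:, :k_used], P[:, :k_used]
    wstar = W @ np.linalg.inv(P.T @ W)

    comp_names = [f"{component_prefix}{i + 1}" for i in range(k_used)]
    T_frame = pd.DataFrame(Xs @ wstar, index=index, columns=comp_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cox = fit_cox(T_frame, outcome)
    risk = predict_lp(cox, T_frame)
    cutpoint = float(np.median(risk))
    group = (risk > cutpoint).astype(float)  # ties at the cutpoint -> low
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        risk_model = fit_cox(risk.to_frame("risk"), outcome)
        split_model = fit_cox(group.to_frame("high_risk"), outcome)
    return PlsCoxModel(
        feature_names=fnames,
        component_names=comp_names,
        x_mean=x_mean,
        x_scale=x_scale,
        wstar=wstar,
        cox=cox,
        risk_model=risk_model,
        split_model=split_model,
        cutpoint=cutpoint,
        n_components=k_used,
    )


def predict_risk(model: PlsCoxModel, X) -> tuple[pd.Series, pd.Series]:
    """Continuous risk and low/high group for new samples of one block.

    Risk is the component-level Cox linear predictor; the group splits at
    the training-median cutpoint, ties going to the low-risk group.
    """
    T = model.predict_components(X)
    if isinstance(T, pd.DataFrame):
        risk = predict_lp(model.cox, T)
    else:
        risk = pd.Series(predict_lp(model.cox, T))
    group = pd.Series(
        np.where(risk > model.cutpoint, "high", "low"), index=risk.index, name="group"
    )
    risk.name = "risk"
    return risk, group
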