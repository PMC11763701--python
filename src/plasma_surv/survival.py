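"""Proportional-hazards fitting, Kaplan-Meier curves, log-rank tests,
concordance, and AIC-based backward elimination.

The Cox fitter is implemented directly (Newton-Raphson on the Efron partial
likelihood) because the PLS Cox construction upstream performs thousands of
small adjusted fits per block; the engine precomputes the risk-set structure
once per outcome and is vectorized over samples.  Kaplan-Meier estimation,
log-rank testing and Harrell's concordance delegate to lifelines behind
thin result types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

from .omics import SurvivalOutcome

logger = logging.getLogger("plasma_surv")

#: absolute cap on a Cox coefficient; hitting it flags monotone likelihood
COEF_CAP = 15.0
NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 50


# ---------------------------------------------------------------------------
# result types


@dataclass
class CoxModel:
    """A fitted proportional-hazards model.

    Coefficients are log hazard ratios; ``summary()`` reports them in the
    conventional table layout (coef, exp(coef), se(coef), z, p).
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    means: np.ndarray  # training predictor means, used to center predictions
    n: int
    n_events: int
    ties: str = "efron"
    converged: bool = True
    separation: bool = False
    dropped: list[str] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.coef / self.se, np.nan)

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * len(self.coef)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "exp(coef)": np.exp(self.coef),
                "se(coef)": self.se,
                "z": self.z,
                "p": self.p,
            },
            index=pd.Index(self.names, name="predictor"),
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "means": self.means.tolist(),
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
            "converged": self.converged,
            "separation": self.separation,
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoxModel":
        d = dict(d)
        for k in ("coef", "se", "means"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class KMCurve:
    """Product-limit survival estimate: S(t) with at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )

    def to_csv(self, path, **kwargs) -> None:
        self.to_frame().to_csv(path, index=False, **kwargs)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p_value": self.p_value}


# ---------------------------------------------------------------------------
# partial-likelihood engine


class CoxEngine:
    """Precomputed risk-set structure for one outcome.

    Samples are sorted by decreasing time so every risk set is a prefix;
    loglik/gradient/information are evaluated with cumulative sums.  Tied
    event times use the Efron correction; with distinct event times this
    reduces exactly to the untied (Breslow = Efron) form, evaluated on a
    fully vectorized path.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        # stable descending sort; censored-at-t stays at risk through t, so
        # the risk set for t is the prefix up to the last index with time >= t
        self.order = np.argsort(-time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order].astype(bool)
        self.n = len(time)
        self.n_events = int(event.sum())
        ev_times = self.time[self.event]
        uniq, counts = np.unique(ev_times, return_counts=True)
        self.has_ties = bool((counts > 1).any())
        # prefix length covering {time >= t} for each event, via the
        # ascending view of -time
        neg = -self.time
        self.ev_pos = np.flatnonzero(self.event)
        self.risk_end = np.searchsorted(neg, -self.time[self.ev_pos], side="right") - 1
        if self.has_ties:
            self.groups = []
            for t in uniq:
                members = self.ev_pos[self.time[self.ev_pos] == t]
                end = np.searchsorted(neg, -t, side="right") - 1
                self.groups.append((end, members))

    def loglik(self, X: np.ndarray, beta: np.ndarray) -> float:
        return self._eval(X, beta, want_derivs=False)[0]

    def loglik_grad_info(self, X: np.ndarray, beta: np.ndarray):
        return self._eval(X, beta, want_derivs=True)

    def _eval(self, X: np.ndarray, beta: np.ndarray, want_derivs: bool):
        # X must already be in engine (sorted) order
        n, p = X.shape
        lp = X @ beta
        shift = lp.max() if n else 0.0  # partial likelihood is shift-invariant
        e = np.exp(lp - shift)
        cum_e = np.cumsum(e)
        if want_derivs:
            xe = X * e[:, None]
            cum_xe = np.cumsum(xe, axis=0)
            cum_xxe = np.cumsum(xe[:, :, None] * X[:, None, :], axis=0)

        ev = self.ev_pos
        if not self.has_ties:
            k = self.risk_end
            S0 = cum_e[k]
            ll = float(np.sum(lp[ev] - shift - np.log(S0)))
            if not want_derivs:
                return (ll,)
            S1 = cum_xe[k]
            r1 = S1 / S0[:, None]
            grad = X[ev].sum(axis=0) - r1.sum(axis=0)
            S2 = cum_xxe[k]
            info = (S2 / S0[:, None, None]).sum(axis=0) - np.einsum(
                "ij,ik->jk", r1, r1
            )
            return ll, grad, info

        ll = float(np.sum(lp[ev] - shift))
        grad = X[ev].sum(axis=0) if want_derivs else None
        info = np.zeros((p, p)) if want_derivs else None
        for end, members in self.groups:
            d = len(members)
            S0 = cum_e[end]
            s0 = e[members].sum()
            if want_derivs:
                S1 = cum_xe[end]
                s1 = xe[members].sum(axis=0)
                S2 = cum_xxe[end]
                s2 = (xe[members][:, :, None] * X[members][:, None, :]).sum(axis=0)
            for j in range(d):
                f = j / d
                denom = S0 - f * s0
                ll -= np.log(denom)
                if want_derivs:
                    r1 = (S1 - f * s1) / denom
                    grad -= r1
                    info += (S2 - f * s2) / denom - np.outer(r1, r1)
        if not want_derivs:
            return (ll,)
        return ll, grad, info


def _newton(engine: CoxEngine, Xs: np.ndarray):
    """Maximize the partial likelihood; returns (beta, loglik, info, flags)."""
    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, info = engine.loglik_grad_info(Xs, beta)
    converged = False
    separation = False
    for _ in range(NEWTON_MAX_ITER):
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(info) @ grad
        if not np.all(np.isfinite(delta)):
            delta = np.linalg.pinv(info) @ grad
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            np.clip(cand, -COEF_CAP, COEF_CAP, out=cand)
            ll_new = engine.loglik(Xs, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        if np.any(np.abs(cand) >= COEF_CAP):
            separation = True
        change = ll_new - ll
        beta = cand
        ll_prev = ll
        ll, grad, info = engine.loglik_grad_info(Xs, beta)
        if abs(change) < NEWTON_TOL:
            converged = True
            break
    return beta, ll, info, converged, separation


# ---------------------------------------------------------------------------
# public operations


def _as_xy(X, outcome: SurvivalOutcome):
    """Coerce predictors to an aligned (values, names, sample_index) triple."""
    if isinstance(X, pd.Series):
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        if isinstance(X.index, pd.RangeIndex) and len(X) == len(outcome):
            X = X.set_axis(outcome.samples)  # positional alignment
        else:
            missing = outcome.samples.difference(X.index)
            if len(missing) == len(outcome.samples):
                raise ValueError(
                    "no overlap between predictor rows and outcome samples"
                )
            X = X.reindex(outcome.samples)
        return X.to_numpy(dtype=float), [str(c) for c in X.columns], outcome
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(outcome):
        raise ValueError(
            f"predictor matrix has {X.shape[0]} rows but outcome has "
            f"{len(outcome)} samples"
        )
    return X, [f"x{i}" for i in range(X.shape[1])], outcome


def fit_cox(X, outcome: SurvivalOutcome, names: list[str] | None = None) -> CoxModel:
    """Fit a Cox proportional-hazards model by maximizing the Efron partial
    likelihood with Newton-Raphson.

    ``X`` is a samples x predictors DataFrame (rows aligned to the outcome by
    sample id) or array.  Samples with any missing predictor value are
    dropped with a logged count; zero-variance predictors are dropped with a
    warning; monotone likelihood (separation) caps the coefficient at
    ``COEF_CAP`` and sets the ``separation`` flag.
    """
    vals, auto_names, outcome = _as_xy(X, outcome)
    names = list(names) if names is not None else auto_names

    row_ok = np.isfinite(vals).all(axis=1) if vals.size else np.ones(len(outcome), bool)
    if not row_ok.all():
        logger.info("fit_cox: dropping %d sample(s) with missing predictors",
                    int((~row_ok).sum()))
    vals = vals[row_ok]
    time = outcome.time.to_numpy()[row_ok]
    event = outcome.event.to_numpy()[row_ok]
    n = len(time)
    if n == 0:
        raise ValueError("no complete samples to fit on")
    if event.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")

    dropped: list[str] = []
    if vals.shape[1]:
        sd = vals.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [nm for nm, k in zip(names, keep) if not k]
            warnings.warn(
                f"fit_cox: dropping zero-variance predictor(s) {dropped}",
                stacklevel=2,
            )
            vals = vals[:, keep]
            names = [nm for nm, k in zip(names, keep) if k]

    means = vals.mean(axis=0) if vals.shape[1] else np.zeros(0)
    Xc = vals - means

    engine = CoxEngine(time, event)
    ll_null = engine.loglik(np.zeros((n, 0)), np.zeros(0))
    if Xc.shape[1] == 0:
        return CoxModel(
            names=[], coef=np.zeros(0), se=np.zeros(0), loglik=ll_null,
            loglik_null=ll_null, means=means, n=n, n_events=int(event.sum()),
            dropped=dropped,
        )

    Xs = Xc[engine.order]
    beta, ll, info, converged, separation = _newton(engine, Xs)
    if separation:
        warnings.warn(
            "fit_cox: monotone partial likelihood (separation); "
            f"coefficient(s) capped at |{COEF_CAP}|",
            stacklevel=2,
        )
    if not converged and not separation:
        warnings.warn("fit_cox: Newton-Raphson did not converge", stacklevel=2)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    se = np.sqrt(var)
    return CoxModel(
        names=names, coef=beta, se=se, loglik=ll, loglik_null=ll_null,
        means=means, n=n, n_events=int(event.sum()),
        converged=converged, separation=separation, dropped=dropped,
    )


def predict_lp(model: CoxModel, X) -> pd.Series | np.ndarray:
    """Linear predictor (log relative hazard) centered at the training
    predictor means: ``lp = (X - means) . coef``."""
    if isinstance(X, pd.DataFrame):
        unknown = [c for c in model.names if c not in X.columns]
        if unknown:
            raise ValueError(f"predictors missing from input: {unknown}")
        vals = X[model.names].to_numpy(dtype=float)
        lp = (vals - model.means) @ model.coef
        return pd.Series(lp, index=X.index, name="lp")
    vals = np.asarray(X, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    if vals.shape[1] != len(model.names):
        raise ValueError(
            f"expected {len(model.names)} predictors, got {vals.shape[1]}"
        )
    return (vals - model.means) @ model.coef


def kaplan_meier(outcome: SurvivalOutcome) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate of the survival function.

    A sample censored at an event time is kept at risk through that time.
    """
    if len(outcome) == 0:
        raise ValueError("empty outcome")
    kmf = KaplanMeierFitter()
    kmf.fit(outcome.time, outcome.event)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    return KMCurve(
        times=table.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
    )


def log_rank(outcome: SurvivalOutcome, groups: pd.Series) -> LogRankResult:
    """k-sample log-rank test of survival differences between groups
    (observed-minus-expected chi-square with k-1 degrees of freedom)."""
    groups = pd.Series(groups).reindex(outcome.samples)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    k = groups.nunique()
    if k < 2:
        raise ValueError("log-rank test needs at least two nonempty groups")
    res = multivariate_logrank_test(
        outcome.time.to_numpy(), groups.to_numpy(), outcome.event.to_numpy()
    )
    stat = float(max(res.test_statistic, 0.0))
    p = float(min(max(res.p_value, np.nextafter(0, 1)), 1.0))
    return LogRankResult(statistic=stat, df=k - 1, p_value=p)


def concordance(outcome: SurvivalOutcome, risk) -> float:
    """Harrell's concordance of a risk score with the outcome, oriented so
    that higher risk means earlier event; tied risks contribute 1/2."""
    risk = np.asarray(risk, dtype=float)
    if not np.isfinite(risk).all():
        raise ValueError("risk scores must be finite")
    try:
        return float(
            _lifelines_cindex(
                outcome.time.to_numpy(), -risk, outcome.event.to_numpy()
            )
        )
    except ZeroDivisionError as exc:
        raise ValueError("no usable (comparable) pairs for concordance") from exc


def stepwise_aic(X: pd.DataFrame, outcome: SurvivalOutcome) -> CoxModel:
    """Backward elimination on the Akaike Information Criterion.

    Starting from the full model, repeatedly refit without each remaining
    predictor and drop the one whose removal lowers the AIC the most, until
    no removal lowers it.  Removal down to the null (empty) model is
    allowed.  Deterministic given column order; AIC ties drop the earliest
    column.
    """
    current = fit_cox(X, outcome)
    cols = list(current.names)
    while cols:
        best_aic = current.aic
        best_j = None
        best_model = None
        for j in range(len(cols)):
            reduced = [c for i, c in enumerate(cols) if i != j]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = fit_cox(X[reduced], outcome)
            if cand.aic < best_aic - 1e-10:
                best_aic = cand.aic
                best_j = j
                best_model = cand
        if best_j is None:
            break
        logger.info("stepwise_aic: dropping %r (AIC %.3f -> %.3f)",
                    cols[best_j], current.aic, best_aic)
        del cols[best_j]
        current = best_model
    return current
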