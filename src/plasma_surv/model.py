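"""The integrated multi-omics survival model.

The algorithm combines omics blocks measured on partially overlapping sets
of samples into a single proportional-hazards model:

1.  fit survival-predictive PLS components separately on every block, using
    only that block's assayed samples;
2.  for every ordered (target, source) pair of blocks, learn to re-express
    the target's components in the source's features by PLS linear
    regression on the samples assayed on both, so each component can be
    predicted for any sample assayed anywhere;
3.  average the per-source predictions of each component, ignoring sources
    on which a sample was not assayed;
4.  fit a Cox model on all averaged components and prune it by backward AIC
    elimination; the linear predictor is the risk score, dichotomized at
    the training median for Kaplan-Meier display and log-rank evaluation.

:class:`Plasma` is the model object built from a
:class:`~plasma_surv.omics.MultiOmicsCollection`; ``fit()`` returns a
:class:`PlasmaResults` carrying estimates, diagnostics, and prediction /
interpretation methods.  The step functions (:func:`fit_single_models`,
:func:`fit_extensions`, :func:`predict_components`, :func:`fit_final`,
:func:`plasma_fit`, :func:`plasma_predict`) are also usable directly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .impute import impute_collection
from .omics import MultiOmicsCollection, SurvivalOutcome, load_manifest
from .pls import (
    AffineComponentMap,
    PlsCoxModel,
    PlsLinearModel,
    default_n_components,
    fit_pls_cox,
    fit_pls_linear,
    load_component_model,
)
from .survival import (
    CoxModel,
    KMCurve,
    LogRankResult,
    fit_cox,
    kaplan_meier,
    log_rank,
    predict_lp,
    stepwise_aic,
)

logger = logging.getLogger("plasma_surv")


@dataclass
class PlasmaConfig:
    """Tunable settings of the integration pipeline.

    ``n_components`` overrides the per-block component count (block name ->
    K); by default K = max(2, ceil(log10(block width))).  Pair models are
    only fitted when the two blocks share at least ``min_intersection``
    assayed samples.  ``include_self_pairs`` keeps each block's own exact
    component map among the averaged sources (one prediction per block).
    """

    n_components: dict | None = None
    min_intersection: int = 10
    include_self_pairs: bool = True
    imputer: str = "sampling"

    def k_for(self, block_name: str, n_features: int) -> int:
        if self.n_components and block_name in self.n_components:
            return int(self.n_components[block_name])
        return default_n_components(n_features)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SingleOmicsModel:
    """One block's PLS Cox model plus its component scores, defined exactly
    on that block's assayed training samples."""

    name: str
    pls: PlsCoxModel
    scores: pd.DataFrame  # assayed samples x component names

    @property
    def component_names(self) -> list[str]:
        return list(self.pls.component_names)


@dataclass
class Extension:
    """A model predicting one block's components from one source block."""

    target: str
    source: str
    model: PlsLinearModel | AffineComponentMap
    n_train: int


@dataclass
class ExtensionSet:
    """All per-source extension models for one target block's components."""

    target: str
    models: dict  # source name -> Extension


@dataclass
class ComponentMatrix:
    """Averaged component scores over the sample universe, with the number
    of contributing source blocks per cell."""

    values: pd.DataFrame  # samples x components
    n_sources: pd.DataFrame  # same shape, int

    @property
    def component_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]


# ---------------------------------------------------------------------------
# pipeline steps


def fit_single_models(
    train: MultiOmicsCollection, config: PlasmaConfig | None = None
) -> list[SingleOmicsModel]:
    """Fit a PLS Cox model per block on its assayed samples.

    Components are named ``<block><index>`` (MAF1, miRSeq3, ...).  A block
    whose assayed samples contain zero events cannot support a Cox model
    and is excluded with a warning.
    """
    config = config or PlasmaConfig()
    singles = []
    for ds in train.datasets:
        samples = ds.assayed_samples
        out = train.outcome.subset(samples)
        if out.n_events == 0:
            warnings.warn(
                f"block {ds.name!r}: zero events among assayed samples; "
                "excluded from single-omics modelling",
                stacklevel=2,
            )
            continue
        X = ds.values.loc[:, samples].T
        K = config.k_for(ds.name, ds.n_features)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls = fit_pls_cox(X, out, n_components=K, component_prefix=ds.name)
        scores = pls.predict_components(X)
        singles.append(SingleOmicsModel(name=ds.name, pls=pls, scores=scores))
    if not singles:
        raise ValueError("no block could be modelled (zero events everywhere)")
    return singles


def fit_extensions(
    train: MultiOmicsCollection,
    singles: list[SingleOmicsModel],
    config: PlasmaConfig | None = None,
) -> list[ExtensionSet]:
    """For every ordered (target, source) block pair, learn to predict the
    target's components from the source's features on the samples assayed
    on both.

    The self pair uses the target's own exact feature-to-component map (its
    components *are* linear in its features), so each component gets one
    prediction per block.  Cross pairs fit a PLS linear regression with
    K = max(2, ceil(log10(source width))) components; pairs whose
    intersection is below ``min_intersection`` are skipped with a warning.
    """
    config = config or PlasmaConfig()
    ext_sets = []
    for tgt in singles:
        tgt_ds = train.block(tgt.name)
        tgt_assayed = tgt_ds.assayed
        models: dict = {}
        for src_ds in train.datasets:
            if src_ds.name == tgt.name:
                if not config.include_self_pairs:
                    continue
                pls = tgt.pls
                amap = AffineComponentMap(
                    feature_names=list(pls.feature_names),
                    response_names=list(pls.component_names),
                    x_mean=pls.x_mean.copy(),
                    x_scale=pls.x_scale.copy(),
                    y_mean=np.zeros(pls.n_components),
                    B=pls.wstar.copy(),
                )
                models[src_ds.name] = Extension(
                    target=tgt.name, source=src_ds.name, model=amap,
                    n_train=int(tgt_assayed.sum()),
                )
                continue
            inter = src_ds.assayed & tgt_assayed
            n_inter = int(inter.sum())
            if n_inter < config.min_intersection:
                warnings.warn(
                    f"extension {tgt.name!r} <- {src_ds.name!r}: only "
                    f"{n_inter} shared samples (< {config.min_intersection}); "
                    "pair skipped",
                    stacklevel=2,
                )
                continue
            shared = inter.index[inter]
            Xsrc = src_ds.values.loc[:, shared].T
            Ytgt = tgt.scores.loc[shared]
            K = config.k_for(src_ds.name, src_ds.n_features)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lin = fit_pls_linear(Xsrc, Ytgt, n_components=K)
            models[src_ds.name] = Extension(
                target=tgt.name, source=src_ds.name, model=lin, n_train=n_inter
            )
        ext_sets.append(ExtensionSet(target=tgt.name, models=models))
    return ext_sets


def predict_components(
    coll: MultiOmicsCollection, extensions: list[ExtensionSet]
) -> ComponentMatrix:
    """Average the per-source component predictions over every source block
    on which each sample was assayed.

    A cell is missing only when the sample is assayed in no source block
    that carries a pair model for that component's target.
    """
    all_comps: list[str] = []
    for ext_set in extensions:
        for ext in ext_set.models.values():
            all_comps.extend(
                c for c in ext.model.response_names if c not in all_comps
            )
            break
    sums = pd.DataFrame(0.0, index=coll.samples, columns=all_comps)
    counts = pd.DataFrame(0, index=coll.samples, columns=all_comps)
    block_names = set(coll.block_names)
    for ext_set in extensions:
        for source, ext in ext_set.models.items():
            if source not in block_names:
                continue  # block absent from this cohort
            src_ds = coll.block(source)
            samples = src_ds.assayed_samples
            if len(samples) == 0:
                continue
            X = src_ds.values.loc[:, samples].T
            extra = [f for f in X.columns if f not in set(ext.model.feature_names)]
            if extra:
                logger.info(
                    "predict_components[%s<-%s]: ignoring %d feature(s) not "
                    "seen in training", ext.target, source, len(extra),
                )
            preds = ext.model.predict(X)
            comps = list(preds.columns)
            sums.loc[samples, comps] += preds.to_numpy()
            counts.loc[samples, comps] += 1
    values = sums.where(counts > 0) / counts.where(counts > 0)
    return ComponentMatrix(values=values, n_sources=counts)


def fit_final(
    cm: ComponentMatrix, outcome: SurvivalOutcome
) -> tuple[list[str], CoxModel]:
    """Fit a Cox model on every averaged component, then prune by backward
    AIC elimination; returns the retained component names and the final
    model with the conventional (coef, exp(coef), se(coef), z, p) report."""
    X = cm.values
    complete = X.notna().all(axis=1)
    if not complete.all():
        logger.info("fit_final: dropping %d sample(s) with incomplete "
                    "components", int((~complete).sum()))
    Xc = X.loc[complete]
    out = outcome.subset(Xc.index)
    if out.n_events == 0:
        raise ValueError("no events among samples with complete components")
    model = stepwise_aic(Xc, out)
    return list(model.names), model


@dataclass
class PlasmaModel:
    """Everything needed to score a new cohort: all single-block models,
    all pair extensions, the retained components with their final Cox
    coefficients, and the training-median risk cutpoint."""

    singles: list[SingleOmicsModel]
    extensions: list[ExtensionSet]
    retained: list[str]
    final_cox: CoxModel
    cutpoint: float
    config: PlasmaConfig
    provenance: dict = field(default_factory=dict)

    @property
    def component_names(self) -> list[str]:
        names: list[str] = []
        for s in self.singles:
            names.extend(s.component_names)
        return names

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "singles": [
                {
                    "name": s.name,
                    "pls": s.pls.to_dict(),
                    "scores": {
                        "index": [str(i) for i in s.scores.index],
                        "columns": list(s.scores.columns),
                        "values": s.scores.to_numpy().tolist(),
                    },
                }
                for s in self.singles
            ],
            "extensions": [
                {
                    "target": es.target,
                    "models": {
                        src: {
                            "n_train": ext.n_train,
                            "model": ext.model.to_dict(),
                        }
                        for src, ext in es.models.items()
                    },
                }
                for es in self.extensions
            ],
            "retained": list(self.retained),
            "final_cox": self.final_cox.to_dict(),
            "cutpoint": self.cutpoint,
            "config": self.config.to_dict(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlasmaModel":
        singles = [
            SingleOmicsModel(
                name=s["name"],
                pls=PlsCoxModel.from_dict(s["pls"]),
                scores=pd.DataFrame(
                    s["scores"]["values"],
                    index=s["scores"]["index"],
                    columns=s["scores"]["columns"],
                ),
            )
            for s in d["singles"]
        ]
        extensions = [
            ExtensionSet(
                target=e["target"],
                models={
                    src: Extension(
                        target=e["target"],
                        source=src,
                        model=load_component_model(m["model"]),
                        n_train=m["n_train"],
                    )
                    for src, m in e["models"].items()
                },
            )
            for e in d["extensions"]
        ]
        return cls(
            singles=singles,
            extensions=extensions,
            retained=list(d["retained"]),
            final_cox=CoxModel.from_dict(d["final_cox"]),
            cutpoint=float(d["cutpoint"]),
            config=PlasmaConfig(**d["config"]),
            provenance=d.get("provenance", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "PlasmaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PlasmaPrediction:
    """Scored cohort: continuous risk, low/high group, the averaged
    component matrix behind them, and (when the outcome is known) the
    log-rank evaluation with per-group Kaplan-Meier curves."""

    risk: pd.Series
    group: pd.Series
    components: ComponentMatrix
    logrank: LogRankResult | None = None
    km_curves: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"risk": self.risk, "group": self.group})


def plasma_fit(
    train: MultiOmicsCollection,
    config: PlasmaConfig | None = None,
    provenance: dict | None = None,
) -> PlasmaModel:
    """Run the full pipeline on an (imputed) training collection."""
    config = config or PlasmaConfig()
    singles = fit_single_models(train, config)
    extensions = fit_extensions(train, singles, config)
    cm = predict_components(train, extensions)
    retained, final = fit_final(cm, train.outcome)
    risk = predict_lp(final, cm.values[retained].dropna())
    cutpoint = float(np.median(risk))
    return PlasmaModel(
        singles=singles,
        extensions=extensions,
        retained=retained,
        final_cox=final,
        cutpoint=cutpoint,
        config=config,
        provenance=provenance or {},
    )


def plasma_predict(
    model: PlasmaModel,
    coll: MultiOmicsCollection,
    evaluate: bool = True,
) -> PlasmaPrediction:
    """Score a new (imputed) cohort with a fitted model.

    The cohort may lack entire blocks; components are then averaged over
    the remaining sources.  Extra features are ignored; a block present
    with training features missing is an error.
    """
    known = {s.name for s in model.singles} | {
        src for es in model.extensions for src in es.models
    }
    if not (known & set(coll.block_names)):
        raise ValueError("cohort shares no omics blocks with the trained model")
    cm = predict_components(coll, model.extensions)
    avail = cm.values[model.retained]
    risk = predict_lp(model.final_cox, avail)
    incomplete = risk.isna()
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} sample(s) received no risk (assayed in "
            "no source block with a pair model)",
            stacklevel=2,
        )
    group = pd.Series(
        np.where(risk > model.cutpoint, "high", "low"), index=risk.index,
        name="group",
    )
    group[incomplete] = np.nan
    logrank = None
    km_curves = None
    if evaluate:
        ok = ~incomplete
        out = coll.outcome.subset(risk.index[ok])
        if ok.any() and group[ok].nunique() >= 2:
            logrank = log_rank(out, group[ok])
            km_curves = {
                g: kaplan_meier(out.subset(out.samples[(group[ok] == g).to_numpy()]))
                for g in ("low", "high")
            }
    return PlasmaPrediction(
        risk=risk, group=group, components=cm, logrank=logrank,
        km_curves=km_curves,
    )


# ---------------------------------------------------------------------------
# model-object surface


class Plasma:
    """Supervised multi-omics survival integration.

    Parameters
    ----------
    collection : MultiOmicsCollection
        Harmonized blocks plus outcome (see :func:`~plasma_surv.omics.harmonize`).
    config : PlasmaConfig, optional
        Pipeline settings; defaults are sensible for omics-scale blocks.

    Examples
    --------
    >>> model = Plasma(collection)
    >>> res = model.fit(seed=17)
    >>> print(res.summary())
    >>> scored = res.predict(test_collection)
    """

    def __init__(
        self, collection: MultiOmicsCollection, config: PlasmaConfig | None = None
    ):
        self.collection = collection
        self.config = config or PlasmaConfig()

    @classmethod
    def from_manifest(cls, path, config: PlasmaConfig | None = None) -> "Plasma":
        """Build the model from a YAML study manifest (see
        :func:`~plasma_surv.omics.load_manifest`)."""
        return cls(load_manifest(path), config=config)

    def fit(self, seed: int = 0) -> "PlasmaResults":
        """Impute low-level missing cells, run the pipeline, and return the
        fitted results.  ``seed`` drives the sampling imputer only; with the
        mean/mode imputer the fit is fully deterministic."""
        imputed, reports = impute_collection(
            self.collection, method=self.config.imputer, seed=seed
        )
        provenance = {
            "imputer": self.config.imputer,
            "seed": seed,
            "imputation": [r.to_dict() for r in reports],
        }
        pm = plasma_fit(imputed, self.config, provenance=provenance)
        return PlasmaResults(self, pm, imputed)


class PlasmaResults:
    """Results of a fitted multi-omics survival integration.

    Attributes
    ----------
    params, bse, zvalues, pvalues : pandas.Series
        Final Cox coefficients (log hazard ratios) on the retained
        components and their uncertainties.
    risk, group : pandas.Series
        Training risks and their median dichotomization.
    """

    def __init__(
        self,
        model: Plasma | None,
        plasma_model: PlasmaModel,
        train_collection: MultiOmicsCollection | None = None,
    ):
        self.model = model
        self.plasma_model = plasma_model
        self._train = train_collection
        self._train_pred: PlasmaPrediction | None = None

    # -- estimates ----------------------------------------------------------

    @property
    def retained_components(self) -> list[str]:
        return list(self.plasma_model.retained)

    @property
    def component_names(self) -> list[str]:
        return self.plasma_model.component_names

    @property
    def params(self) -> pd.Series:
        fc = self.plasma_model.final_cox
        return pd.Series(fc.coef, index=fc.names, name="coef")

    @property
    def bse(self) -> pd.Series:
        fc = self.plasma_model.final_cox
        return pd.Series(fc.se, index=fc.names, name="se(coef)")

    @property
    def zvalues(self) -> pd.Series:
        fc = self.plasma_model.final_cox
        return pd.Series(fc.z, index=fc.names, name="z")

    @property
    def pvalues(self) -> pd.Series:
        fc = self.plasma_model.final_cox
        return pd.Series(fc.p, index=fc.names, name="p")

    @property
    def aic(self) -> float:
        return self.plasma_model.final_cox.aic

    @property
    def cutpoint(self) -> float:
        return self.plasma_model.cutpoint

    # -- training-set diagnostics ------------------------------------------

    def _training_prediction(self) -> PlasmaPrediction:
        if self._train_pred is None:
            if self._train is None:
                raise ValueError("training collection not available (loaded model?)")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._train_pred = plasma_predict(self.plasma_model, self._train)
        return self._train_pred

    @property
    def risk(self) -> pd.Series:
        return self._training_prediction().risk

    @property
    def group(self) -> pd.Series:
        return self._training_prediction().group

    @property
    def train_logrank(self) -> LogRankResult:
        return self._training_prediction().logrank

    # -- scoring ------------------------------------------------------------

    def predict(
        self, collection: MultiOmicsCollection | None = None, seed: int = 0
    ) -> PlasmaPrediction:
        """Score a cohort (default: the training collection).  Low-level
        missing cells are imputed with the configured method first."""
        if collection is None:
            return self._training_prediction()
        cfg = self.plasma_model.config
        imputed, _ = impute_collection(collection, method=cfg.imputer, seed=seed)
        return plasma_predict(self.plasma_model, imputed)

    # -- interpretation -----------------------------------------------------

    def composite_weights(self):
        from .interpret import composite_weights

        return composite_weights(self.plasma_model)

    def top_features(self, fraction: float = 0.05):
        from .interpret import top_features

        return top_features(self.composite_weights(), fraction)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        pm = self.plasma_model
        lines = []
        lines.append("Multi-omics PLS Cox survival integration")
        lines.append("=" * 56)
        fc = pm.final_cox
        lines.append(f"Samples used in final model: {fc.n} ({fc.n_events} events)")
        blocks = ", ".join(
            f"{s.name}[{len(s.pls.feature_names)}f/K={s.pls.n_components}]"
            for s in pm.singles
        )
        lines.append(f"Blocks: {blocks}")
        lines.append(
            f"Components: {len(pm.component_names)} total, "
            f"{len(pm.retained)} retained after backward AIC elimination"
        )
        lines.append(f"Final model AIC: {fc.aic:.2f}   "
                     f"log partial likelihood: {fc.loglik:.2f}")
        lines.append(f"Training median risk cutpoint: {pm.cutpoint:.4f}")
        lines.append("")
        lines.append("Retained components:")
        lines.append(fc.summary().to_string(float_format=lambda v: f"{v:.4f}"))
        if self._train is not None:
            try:
                lr = self.train_logrank
                if lr is not None:
                    lines.append("")
                    lines.append(
                        f"Training log-rank (low vs high risk): chi2 = "
                        f"{lr.statistic:.2f}, df = {lr.df}, p = {lr.p_value:.3g}"
                    )
            except ValueError:
                pass
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_km(self, prediction: PlasmaPrediction | None = None, ax=None):
        """Kaplan-Meier curves of the low- and high-risk groups."""
        from .plot import plot_km_groups

        pred = prediction if prediction is not None else self._training_prediction()
        if pred.km_curves is None:
            raise ValueError("prediction carries no evaluation (outcome unknown)")
        return plot_km_groups(pred.km_curves, ax=ax)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        self.plasma_model.save(path)

    @classmethod
    def load(cls, path) -> "PlasmaResults":
        return cls(None, PlasmaModel.load(path))
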