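"""Synthetic multi-omics survival studies.

The generator emulates the data regime the integration pipeline is designed
for: several feature blocks of very different widths driven by a shared
low-dimensional risk signal, whole samples unassayed on some platforms,
sporadic missing cells within assayed samples, and right-censored
exponential survival whose hazard depends on the latent factors.

Latent factors Z are standard normal; continuous block values are
``loadings . Z`` plus Gaussian noise; binary (mutation-like) blocks
threshold the same latent construction at a per-feature quantile so the
positivity rate is controlled.  Event times are exponential (optionally
Weibull) with hazard proportional to ``exp(effects . Z)``; censoring is an
independent exponential whose rate is tuned to hit the requested censoring
fraction in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .omics import MultiOmicsCollection, OmicsDataset, SurvivalOutcome, harmonize

logger = logging.getLogger("plasma_surv")


@dataclass
class BlockSpec:
    """Shape and type of one simulated omics block."""

    name: str
    n_features: int
    kind: str = "continuous"  # or "binary"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown block kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults describe the reference design used throughout the test suite:
    three continuous blocks of 50/200/500 features, two latent factors each
    with log hazard-ratio effect 1.0, 30% per-block sample dropout, 20%
    censoring, and a small (2%) rate of missing cells within assayed
    samples.
    """

    n_samples: int = 500
    blocks: tuple = (
        BlockSpec("alpha", 50),
        BlockSpec("beta", 200),
        BlockSpec("gamma", 500),
    )
    n_factors: int = 2
    factor_effects: tuple = (1.0, 1.0)  # log hazard ratio per factor
    loading_sparsity: float = 0.3  # fraction of nonzero feature loadings
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    block_dropout: float = 0.3  # fraction of samples unassayed per block
    cell_missing: float = 0.02  # missing-cell rate within assayed samples
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.2
    binary_positive_rate: float = 0.1
    weibull_shape: float = 1.0  # 1.0 = exponential
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.factor_effects) != self.n_factors:
            raise ValueError("factor_effects length must equal n_factors")
        for name in ("loading_sparsity", "block_dropout", "cell_missing",
                     "censoring_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass
class SimulatedStudy:
    """A generated study plus the ground truth behind it."""

    collection: MultiOmicsCollection
    factors: pd.DataFrame  # samples x latent factors
    log_hazard: pd.Series  # true per-sample log relative hazard
    config: SimulationConfig = field(repr=False, default=None)


def _censoring_rate_constant(event_times: np.ndarray, target: float) -> float:
    """Rate c of an independent exponential censor such that the expected
    censored fraction over the drawn event times equals ``target``:
    ``mean(1 - exp(-c * T_i)) == target``."""

    def frac(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(-np.expm1(-c * event_times))) - target

    lo, hi = np.log(1.0 / event_times.max()) - 20.0, np.log(1.0 / event_times.min()) + 20.0
    return float(np.exp(optimize.brentq(frac, lo, hi)))


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate one multi-omics survival study.

    Bit-identical under a fixed ``config.seed``.  Every sample is
    guaranteed to stay assayed in at least one block: a sample whose
    dropout draw removed it everywhere has its dropout re-drawn (logged).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    Z = rng.standard_normal((n, config.n_factors))
    effects = np.asarray(config.factor_effects, dtype=float)
    log_hazard = Z @ effects
    rates = config.baseline_hazard * np.exp(log_hazard)

    # event times: exponential, or Weibull via inverse-transform on the
    # cumulative hazard H(t) = rate * t^shape
    u = rng.uniform(size=n)
    shape = config.weibull_shape
    T = (-np.log(u) / rates) ** (1.0 / shape)
    if config.censoring_rate > 0:
        c = _censoring_rate_constant(T, config.censoring_rate)
        C = rng.exponential(scale=1.0 / c, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time = T
        event = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)

    # block-level dropout with the everywhere-unassayed guard
    n_blocks = len(config.blocks)
    assayed = rng.uniform(size=(n, n_blocks)) >= config.block_dropout
    redrawn = 0
    for i in range(n):
        while not assayed[i].any():
            assayed[i] = rng.uniform(size=n_blocks) >= config.block_dropout
            redrawn += 1
    if redrawn:
        logger.info("simulate_study: re-drew dropout for samples unassayed "
                    "everywhere (%d redraw(s))", redrawn)

    datasets = []
    for b, spec in enumerate(config.blocks):
        p = spec.n_features
        mask = rng.uniform(size=(p, config.n_factors)) < config.loading_sparsity
        loadings = np.where(
            mask, rng.normal(scale=config.loading_scale, size=(p, config.n_factors)), 0.0
        )
        latent = Z @ loadings.T + rng.normal(scale=config.noise_sd, size=(n, p))
        if spec.kind == "binary":
            thresh = np.quantile(latent, 1.0 - config.binary_positive_rate, axis=0)
            values = (latent > thresh).astype(float)
        else:
            values = latent
        values = values.T  # features x samples
        vals = pd.DataFrame(
            values,
            index=[f"{spec.name}_f{j + 1}" for j in range(p)],
            columns=sample_ids,
        )
        # low-level missing cells within assayed samples
        if config.cell_missing > 0:
            miss = rng.uniform(size=vals.shape) < config.cell_missing
            vals = vals.mask(miss)
            # keep every feature observable somewhere among assayed samples
            assayed_cols = np.flatnonzero(assayed[:, b])
            sub = vals.iloc[:, assayed_cols]
            wiped = np.flatnonzero(sub.isna().all(axis=1).to_numpy())
            for j in wiped:
                col = assayed_cols[int(rng.integers(len(assayed_cols)))]
                restore = latent[col, j] if spec.kind == "continuous" else values[j, col]
                vals.iat[j, col] = restore
        vals.loc[:, ~assayed[:, b]] = np.nan  # unassayed samples: all-missing
        datasets.append(OmicsDataset(spec.name, vals))

    outcome = SurvivalOutcome(
        pd.Series(time, index=sample_ids, name="time"),
        pd.Series(event, index=sample_ids, name="event"),
    )
    collection = harmonize(datasets, outcome)
    return SimulatedStudy(
        collection=collection,
        factors=pd.DataFrame(
            Z, index=sample_ids,
            columns=[f"factor{k + 1}" for k in range(config.n_factors)],
        ),
        log_hazard=pd.Series(log_hazard, index=sample_ids, name="log_hazard"),
        config=config,
    )


def write_study(study: SimulatedStudy, directory) -> "Path":
    """Write a study in the TSV + YAML-manifest format the readers consume;
    returns the manifest path (the round trip is itself a test)."""
    from pathlib import Path

    import yaml

    from .omics import write_omics_matrix, write_outcome

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"outcome": "outcome.tsv", "blocks": []}
    for ds, spec in zip(study.collection.datasets, study.config.blocks):
        fname = f"{ds.name}.tsv"
        write_omics_matrix(ds, directory / fname)
        manifest["blocks"].append(
            {"name": ds.name, "file": fname, "type": spec.kind}
        )
    write_outcome(study.collection.outcome, directory / "outcome.tsv")
    mpath = directory / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath
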