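"""Low-level imputation of missing cells within assayed samples.

PLS models refuse to score a sample that is missing even one feature value,
so any sample that carries *some* data in a block must be completed before
modelling.  Two deliberately simple imputers are provided; in this setting
the choice of imputer has little influence on the downstream predictive
models, which average over many features.

Whole-sample missingness (a sample never assayed on a platform) is a
different phenomenon and is left untouched: unassayed columns stay
all-missing and are handled by the cross-extension machinery instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .omics import MultiOmicsCollection, OmicsDataset


@dataclass
class ImputationReport:
    """What an imputer did to one block."""

    block: str
    method: str
    n_imputed: int
    n_missing_unassayed: int  # cells left missing in unassayed columns
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "block": self.block,
            "method": self.method,
            "n_imputed": self.n_imputed,
            "n_missing_unassayed": self.n_missing_unassayed,
            "seed": self.seed,
        }


def _check_observed(vals: pd.DataFrame, block: str) -> None:
    n_obs = vals.notna().sum(axis=1)
    if (n_obs == 0).any():
        bad = vals.index[n_obs == 0].tolist()
        raise ValueError(
            f"block {block!r}: feature(s) {bad[:5]} have no observed values "
            "among assayed samples; filter them out before imputing"
        )


def _mode_smallest(obs: np.ndarray) -> float:
    vals, counts = np.unique(obs, return_counts=True)
    return float(vals[np.argmax(counts)])  # np.unique sorts: ties -> smallest


def mean_mode_impute(ds: OmicsDataset) -> tuple[OmicsDataset, ImputationReport]:
    """Fill each missing cell of an assayed sample with the feature's mean
    (continuous behaviour, more than five distinct observed values) or mode
    (binary / small categorical, ties broken by the smallest value).

    Observed cells, feature order and assayed flags are never altered;
    unassayed samples remain all-missing.
    """
    assayed = ds.assayed
    cols = assayed.index[assayed]
    vals = ds.values.loc[:, cols]
    _check_observed(vals, ds.name)
    out = ds.values.copy()
    n_imputed = 0
    arr = vals.to_numpy()
    for i, feat in enumerate(vals.index):
        row = arr[i]
        miss = np.isnan(row)
        if not miss.any():
            continue
        obs = row[~miss]
        if len(np.unique(obs)) > 5:
            fill = float(obs.mean())
        else:
            fill = _mode_smallest(obs)
        out.loc[feat, cols[miss]] = fill
        n_imputed += int(miss.sum())
    report = ImputationReport(
        block=ds.name,
        method="mean_mode",
        n_imputed=n_imputed,
        n_missing_unassayed=int(ds.values.loc[:, assayed.index[~assayed]].isna().sum().sum()),
    )
    return OmicsDataset(ds.name, out), report


def sampling_impute(
    ds: OmicsDataset, seed: int = 0
) -> tuple[OmicsDataset, ImputationReport]:
    """Fill each missing cell of an assayed sample with a uniform draw (with
    replacement) from that feature's observed values.

    Reproducible under ``seed``; unassayed samples remain all-missing.
    """
    assayed = ds.assayed
    cols = assayed.index[assayed]
    vals = ds.values.loc[:, cols]
    _check_observed(vals, ds.name)
    rng = np.random.default_rng(seed)
    out = ds.values.copy()
    n_imputed = 0
    arr = vals.to_numpy()
    for i, feat in enumerate(vals.index):
        row = arr[i]
        miss = np.isnan(row)
        if not miss.any():
            continue
        obs = row[~miss]
        out.loc[feat, cols[miss]] = rng.choice(obs, size=int(miss.sum()), replace=True)
        n_imputed += int(miss.sum())
    report = ImputationReport(
        block=ds.name,
        method="sampling",
        n_imputed=n_imputed,
        n_missing_unassayed=int(ds.values.loc[:, assayed.index[~assayed]].isna().sum().sum()),
        seed=seed,
    )
    return OmicsDataset(ds.name, out), report


def impute_collection(
    coll: MultiOmicsCollection, method: str = "sampling", seed: int = 0
) -> tuple[MultiOmicsCollection, list[ImputationReport]]:
    """Impute every block of a collection.

    ``method`` is ``"sampling"`` or ``"mean_mode"``.  With the sampling
    imputer, block *i* uses ``seed + i`` so blocks are independent yet the
    whole collection is reproducible.
    """
    datasets, reports = [], []
    for i, ds in enumerate(coll.datasets):
        if method == "sampling":
            new, rep = sampling_impute(ds, seed=seed + i)
        elif method == "mean_mode":
            new, rep = mean_mode_impute(ds)
        else:
            raise ValueError(f"unknown imputation method {method!r}")
        datasets.append(new)
        reports.append(rep)
    return MultiOmicsCollection(datasets, coll.outcome), reports
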