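"""Multi-omics data containers, I/O, filtering, harmonization, and splitting.

All file interfaces follow the convention of the multi-omics ecosystem:
features are rows, patient samples are columns, and a sample that was never
assayed on a platform appears as a column entirely composed of missing
values.  In memory each block is a pandas DataFrame in the same orientation,
wrapped in :class:`OmicsDataset`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("plasma_surv")

#: tokens (case-insensitive) read as missing values in delimited files
DEFAULT_MISSING_TOKENS = ("", "na", "nan")


@dataclass
class OmicsDataset:
    """One omics block: a features x samples numeric matrix over a shared
    sample universe.

    A sample is *assayed* iff it has at least one observed (non-missing)
    value in this block; unassayed samples are all-missing columns kept in
    place so that every block spans the same universe.
    """

    name: str
    values: pd.DataFrame  # features x samples, float

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        feats = self.values.index
        if feats.has_duplicates:
            dups = feats[feats.duplicated()].unique().tolist()
            raise ValueError(
                f"duplicate feature identifiers in block {self.name!r}: {dups}"
            )
        cols = self.values.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(
                f"duplicate sample identifiers in block {self.name!r}: {dups}"
            )

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def assayed(self) -> pd.Series:
        """Boolean flag per sample: has any observed value in this block."""
        return self.values.notna().any(axis=0)

    @property
    def assayed_samples(self) -> pd.Index:
        a = self.assayed
        return a.index[a]

    def subset_samples(self, samples: Sequence) -> "OmicsDataset":
        return OmicsDataset(self.name, self.values.loc[:, list(samples)].copy())

    def reindex_samples(self, universe: Sequence) -> "OmicsDataset":
        """Pad/reorder columns to *universe*; absent samples become all-missing."""
        return OmicsDataset(self.name, self.values.reindex(columns=list(universe)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OmicsDataset({self.name!r}, {self.n_features} features x "
            f"{len(self.samples)} samples, {int(self.assayed.sum())} assayed)"
        )


@dataclass
class SurvivalOutcome:
    """Right-censored time-to-event outcome per sample.

    ``time`` is a positive duration; ``event`` is 1 if the event was
    observed and 0 if the sample was censored.
    """

    time: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        self.time = pd.Series(self.time, dtype=float)
        self.event = pd.Series(self.event, dtype=int).reindex(self.time.index)
        if self.time.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in outcome")
        if self.time.isna().any() or self.event.isna().any():
            raise ValueError("missing values in outcome table")
        if (self.time <= 0).any():
            bad = self.time.index[self.time <= 0].tolist()
            raise ValueError(f"non-positive survival times for samples {bad}")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")

    @property
    def samples(self) -> pd.Index:
        return self.time.index

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, samples: Sequence) -> "SurvivalOutcome":
        samples = list(samples)
        return SurvivalOutcome(self.time.loc[samples], self.event.loc[samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})


@dataclass
class MultiOmicsCollection:
    """A list of omics blocks over one ordered sample universe plus the
    survival outcome for every sample in the universe."""

    datasets: list[OmicsDataset]
    outcome: SurvivalOutcome

    def __post_init__(self) -> None:
        universe = self.outcome.samples
        for ds in self.datasets:
            if not ds.samples.equals(universe):
                raise ValueError(
                    f"block {ds.name!r} does not share the collection's sample "
                    "universe; run harmonize() first"
                )
        assayed_any = self.assayed_any()
        if not assayed_any.all():
            bad = assayed_any.index[~assayed_any].tolist()
            raise ValueError(f"samples assayed in no block: {bad}")
        names = [ds.name for ds in self.datasets]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate block names: {names}")

    @property
    def samples(self) -> pd.Index:
        return self.outcome.samples

    @property
    def block_names(self) -> list[str]:
        return [ds.name for ds in self.datasets]

    def block(self, name: str) -> OmicsDataset:
        for ds in self.datasets:
            if ds.name == name:
                return ds
        raise KeyError(name)

    def assayed_any(self) -> pd.Series:
        out = pd.Series(False, index=self.samples)
        for ds in self.datasets:
            out |= ds.assayed
        return out

    def subset_samples(self, samples: Sequence) -> "MultiOmicsCollection":
        samples = list(samples)
        return MultiOmicsCollection(
            [ds.subset_samples(samples) for ds in self.datasets],
            self.outcome.subset(samples),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        blocks = ", ".join(
            f"{ds.name}[{ds.n_features}]" for ds in self.datasets
        )
        return (
            f"MultiOmicsCollection({len(self.samples)} samples, "
            f"{self.outcome.n_events} events; blocks: {blocks})"
        )


@dataclass
class FilterSpec:
    """Feature-filtering rules applied per block.

    Every statistic is computed over the observed (non-missing) entries of
    assayed samples only.  ``None`` disables a rule.

    Defaults mirror common practice for each platform type and are all off;
    typical settings: methylation beta values ``min_sd=0.25,
    beta_boundary=0.15``; binary mutation calls ``min_positive_fraction=0.04``;
    expression ``min_sd`` and/or ``min_mean``; clinical tables
    ``max_missing_fraction=0.25, drop_constant=True, drop_duplicates=True``.
    """

    min_sd: float = 0.0
    min_mean: float | None = None
    beta_boundary: float | None = None
    min_positive_fraction: float | None = None
    max_missing_fraction: float = 1.0
    drop_constant: bool = False
    drop_duplicates: bool = False

    def __post_init__(self) -> None:
        for frac_name in ("min_positive_fraction", "max_missing_fraction"):
            v = getattr(self, frac_name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if self.min_sd < 0:
            raise ValueError("min_sd must be nonnegative")


# ---------------------------------------------------------------------------
# readers / writers


def _missing_mask(raw: pd.DataFrame, tokens: Iterable[str]) -> pd.DataFrame:
    toks = {t.lower() for t in tokens}
    return raw.map(lambda v: isinstance(v, str) and v.strip().lower() in toks)


def read_omics_matrix(
    path: str | Path,
    name: str | None = None,
    sep: str | None = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> OmicsDataset:
    """Read a features x samples matrix from delimited text.

    The header row holds sample identifiers, the first column feature
    identifiers.  Cells matching ``missing_tokens`` (case-insensitive) are
    missing; any other non-numeric cell is rejected with its location.
    ``sep=None`` sniffs the delimiter (tab vs comma).
    """
    path = Path(path)
    if name is None:
        name = path.stem
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n")
    if sep is None:
        sep = "\t" if "\t" in header else ","
    sample_ids = header.split(sep)[1:]
    if len(set(sample_ids)) != len(sample_ids):
        seen: set = set()
        dups = sorted({s for s in sample_ids if s in seen or seen.add(s)})
        raise ValueError(f"{path}: repeated sample identifier(s) in header: {dups}")
    raw = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: repeated sample identifier(s) in header: {dup}")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature identifier(s): {dup}")
    missing = _missing_mask(raw, missing_tokens)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & ~missing
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    values = values.where(~missing)
    return OmicsDataset(name, values)


def write_omics_matrix(ds: OmicsDataset, path: str | Path, sep: str = "\t") -> None:
    """Write a block in the paired format of :func:`read_omics_matrix`."""
    ds.values.to_csv(path, sep=sep, na_rep="NA")


def read_outcome(
    path: str | Path,
    sep: str | None = None,
    time_col: str = "time",
    event_col: str = "event",
) -> SurvivalOutcome:
    """Read the (time, event) outcome table keyed by sample identifier."""
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else None,
        engine="python" if sep is None else "c",
        index_col=0,
    )
    missing = [c for c in (time_col, event_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: outcome table lacks column(s) {missing}")
    return SurvivalOutcome(df[time_col], df[event_col])


def write_outcome(outcome: SurvivalOutcome, path: str | Path, sep: str = "\t") -> None:
    outcome.to_frame().to_csv(path, sep=sep, index_label="sample")


# ---------------------------------------------------------------------------
# clinical encoding


def one_hot_encode(
    table: pd.DataFrame,
    max_levels: int = 5,
    binary_name: str = "ClinicalBin",
    continuous_name: str = "ClinicalCont",
) -> tuple[OmicsDataset, OmicsDataset]:
    """Split a mixed clinical table (samples as rows, variables as columns)
    into a binary indicator block and a continuous block.

    A column is treated as categorical when it is non-numeric or has at most
    ``max_levels`` distinct non-missing values.  Each categorical column with
    L observed levels becomes L one-hot indicator features named
    ``column.level``; a sample missing the categorical value is missing in
    every derived indicator.  Continuous columns pass through unchanged.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("empty clinical table")
    bin_rows: dict[str, pd.Series] = {}
    cont_rows: dict[str, pd.Series] = {}
    for col in table.columns:
        s = table[col]
        numeric = pd.to_numeric(s, errors="coerce")
        is_numeric = numeric.notna().equals(s.notna())
        categorical = (not is_numeric) or s.dropna().nunique() <= max_levels
        if categorical:
            obs = s.dropna()
            for level in pd.unique(obs):
                ind = (s == level).astype(float)
                ind[s.isna()] = np.nan
                bin_rows[f"{col}.{level}"] = ind
        else:
            cont_rows[col] = numeric.astype(float)
    binary = OmicsDataset(binary_name, pd.DataFrame(bin_rows, index=table.index).T)
    continuous = OmicsDataset(
        continuous_name, pd.DataFrame(cont_rows, index=table.index).T
    )
    return binary, continuous


# ---------------------------------------------------------------------------
# filtering


def filter_features(ds: OmicsDataset, spec: FilterSpec) -> OmicsDataset:
    """Return the block restricted to features passing every active rule.

    Rules (statistics over observed entries of assayed samples only):

    - ``max_missing_fraction``: drop features missing in more than this
      fraction of assayed samples;
    - ``min_sd``: drop features whose standard deviation is below it;
    - ``min_mean``: drop features whose mean is below it;
    - ``beta_boundary``: drop features whose mean lies within this distance
      of 0 or 1 (for methylation beta values);
    - ``min_positive_fraction``: drop binary features positive in fewer than
      this fraction of assayed samples;
    - ``drop_constant``: drop features with at most one distinct observed
      value;
    - ``drop_duplicates``: drop features whose observed vector exactly
      equals an earlier feature's (keep the first by input order).

    Feature order is preserved and the sample universe is unchanged.
    """
    vals = ds.values.loc[:, ds.assayed_samples]
    n_assayed = vals.shape[1]
    if n_assayed == 0:
        raise ValueError(f"block {ds.name!r} has no assayed samples")
    keep = pd.Series(True, index=ds.features)

    miss_frac = vals.isna().mean(axis=1)
    keep &= miss_frac <= spec.max_missing_fraction
    if spec.min_sd > 0:
        keep &= vals.std(axis=1, ddof=1) >= spec.min_sd
    if spec.min_mean is not None:
        keep &= vals.mean(axis=1) >= spec.min_mean
    if spec.beta_boundary is not None:
        mean = vals.mean(axis=1)
        keep &= (mean >= spec.beta_boundary) & (mean <= 1.0 - spec.beta_boundary)
    if spec.min_positive_fraction is not None:
        pos_frac = (vals > 0).sum(axis=1) / vals.notna().sum(axis=1).clip(lower=1)
        keep &= pos_frac >= spec.min_positive_fraction
    if spec.drop_constant:
        keep &= vals.nunique(axis=1, dropna=True) > 1
    if spec.drop_duplicates:
        keep &= ~vals.duplicated(keep="first")

    if not keep.any():
        raise ValueError(
            f"filtering removed every feature of block {ds.name!r}; "
            "loosen the thresholds"
        )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_features[%s]: dropped %d of %d features",
                    ds.name, n_drop, len(keep))
    return OmicsDataset(ds.name, ds.values.loc[keep.values].copy())


# ---------------------------------------------------------------------------
# harmonization and splitting


def harmonize(
    datasets: Sequence[OmicsDataset], outcome: SurvivalOutcome
) -> MultiOmicsCollection:
    """Align blocks and outcome on one ordered sample universe.

    The universe is every sample that appears in at least one block *and*
    has an outcome, ordered as in the outcome table.  Blocks are padded with
    all-missing columns for universe samples they lack; samples lacking an
    outcome (or assayed in no block) are dropped with a logged count.
    """
    if len(datasets) == 0:
        raise ValueError("harmonize needs at least one omics block")
    if len(outcome) == 0:
        raise ValueError("empty outcome table")
    in_blocks: set = set()
    for ds in datasets:
        in_blocks |= set(ds.assayed_samples)
    n_no_outcome = len(in_blocks - set(outcome.samples))
    if n_no_outcome:
        logger.warning("harmonize: dropping %d sample(s) lacking an outcome",
                       n_no_outcome)
    universe = [s for s in outcome.samples if s in in_blocks]
    n_unassayed = len(outcome) - len(universe)
    if n_unassayed:
        logger.warning("harmonize: dropping %d outcome sample(s) assayed in "
                       "no block", n_unassayed)
    if not universe:
        raise ValueError("no samples shared between the omics blocks and the outcome")
    return MultiOmicsCollection(
        [ds.reindex_samples(universe) for ds in datasets],
        outcome.subset(universe),
    )


def split_train_test(
    coll: MultiOmicsCollection,
    train_fraction: float = 0.6,
    seed: int = 0,
    resplit_on_imbalance: bool = False,
    max_resplits: int = 10,
):
    """Randomly partition the collection into train and test sets.

    Sizes are ``round(train_fraction * n)`` versus the rest; every block is
    sliced consistently.  The returned balance check is the log-rank test of
    train versus test outcome — a report only.  With
    ``resplit_on_imbalance`` the split is retried with seed+1 (logged) while
    the balance p-value is below 0.05, never silently.

    Returns ``(train, test, balance)`` where balance is a
    :class:`~plasma_surv.survival.LogRankResult`.
    """
    from .survival import log_rank  # local import: survival imports omics types

    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(coll.samples)
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty partition at n={n}"
        )
    for attempt in range(max_resplits + 1):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        train_ids = coll.samples[np.sort(perm[:n_train])]
        test_ids = coll.samples[np.sort(perm[n_train:])]
        train = coll.subset_samples(train_ids)
        test = coll.subset_samples(test_ids)
        if train.outcome.n_events == 0 or test.outcome.n_events == 0:
            raise ValueError(
                "split produced a partition with zero events; a proportional-"
                "hazards model cannot be fitted — adjust train_fraction or seed"
            )
        labels = pd.Series("test", index=coll.samples)
        labels[train_ids] = "train"
        balance = log_rank(coll.outcome, labels)
        if balance.p_value >= 0.05 or not resplit_on_imbalance:
            if balance.p_value < 0.05:
                logger.warning(
                    "split_train_test: train/test survival differs "
                    "(log-rank p=%.3g); split kept", balance.p_value,
                )
            return train, test, balance
        logger.warning(
            "split_train_test: imbalance at seed %d (p=%.3g); retrying with "
            "seed %d", seed + attempt, balance.p_value, seed + attempt + 1,
        )
    raise ValueError(f"no balanced split found after {max_resplits} retries")


# ---------------------------------------------------------------------------
# manifest


def load_manifest(path: str | Path):
    """Load a YAML manifest describing a multi-omics study.

    Schema::

        outcome: outcome.tsv          # columns: sample, time, event
        blocks:
          - name: mRNASeq
            file: mrnaseq.tsv
            type: continuous          # or binary
            filter: {min_sd: 1.25, min_mean: 5.0}   # optional FilterSpec

    Paths are relative to the manifest.  Returns a harmonized
    :class:`MultiOmicsCollection` with per-block filters applied.
    """
    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    base = path.parent
    outcome = read_outcome(base / spec["outcome"])
    datasets = []
    for entry in spec["blocks"]:
        ds = read_omics_matrix(base / entry["file"], name=entry["name"])
        if entry.get("filter"):
            ds = filter_features(ds, FilterSpec(**entry["filter"]))
        datasets.append(ds)
    return harmonize(datasets, outcome)
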