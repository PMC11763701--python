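"""Opening the black box: per-feature weights on the final log hazard.

The fitted pipeline is a composition of two linear layers — features to
(averaged) components, and components to the log hazard — so for a fully
assayed sample the risk is itself an affine function of the raw features.
This module materializes that function as one weight per feature per block,
standardizes the weights within each block for cross-platform display, and
exports ranked top-feature lists for gene-enrichment upload.

Positive weight means the feature increases the hazard (worse outcome).
The weights describe the all-sources averaging regime of a fully assayed
sample; when a sample misses blocks, its effective weights differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PlasmaModel


@dataclass
class CompositeWeights:
    """Per-block feature weights on the final log hazard.

    ``weights[block]`` maps each raw feature to its coefficient in the
    composed risk function; ``intercept`` collects every centering constant
    so that for a fully assayed sample
    ``risk = sum_B x_B . weights[B] + intercept``.
    ``standardized[block]`` is the within-block z-score of the weights.
    """

    weights: dict  # block name -> pd.Series (feature -> weight)
    standardized: dict  # block name -> pd.Series
    intercept: float

    def risk_of(self, feature_values: dict) -> float:
        """Risk of one fully assayed sample given ``{block: Series}``."""
        total = self.intercept
        for block, w in self.weights.items():
            x = feature_values[block]
            total += float(x.loc[w.index] @ w)
        return total

    def to_frames(self) -> dict:
        out = {}
        for block, w in self.weights.items():
            df = pd.DataFrame(
                {"weight": w, "standardized": self.standardized[block]}
            )
            df.index.name = "feature"
            out[block] = df
        return out


def composite_weights(model: PlasmaModel) -> CompositeWeights:
    """Compose the extension and Cox layers into per-feature weights.

    For block B, the weight of feature f is::

        sum over retained components c of
            coef(c) / S_c * (affine coefficient of f in the
                             (target-of-c <- B) extension model)

    where S_c is the number of source blocks averaged for component c.  The
    intercepts of the extension maps and the component centering of the
    final Cox model are folded into a single constant.
    """
    if not model.retained and model.final_cox is None:  # pragma: no cover
        raise ValueError("model is not fitted")
    final = model.final_cox
    coef = pd.Series(final.coef, index=final.names)
    means = pd.Series(final.means, index=final.names)

    # every block that can serve as a source anywhere
    blocks: dict[str, pd.Index] = {}
    for es in model.extensions:
        for src, ext in es.models.items():
            blocks.setdefault(src, pd.Index(ext.model.feature_names))

    weights = {
        b: pd.Series(0.0, index=idx, name="weight") for b, idx in blocks.items()
    }
    intercept = 0.0
    for es in model.extensions:
        # components of this target present in the final model
        tgt_comps = None
        for ext in es.models.values():
            tgt_comps = list(ext.model.response_names)
            break
        if not tgt_comps:
            continue
        retained_here = [c for c in tgt_comps if c in coef.index]
        if not retained_here:
            continue
        S = len(es.models)
        for src, ext in es.models.items():
            A, b0 = ext.model.affine()  # (p_src, K_target), (K_target,)
            for c in retained_here:
                k = tgt_comps.index(c)
                weights[src] += (coef[c] / S) * pd.Series(
                    A[:, k], index=blocks[src]
                )
                intercept += float(coef[c] / S * b0[k])
    # final Cox linear predictor is centered at the training component means
    intercept -= float((coef * means).sum())

    standardized = {}
    for b, w in weights.items():
        if len(w) >= 2 and w.std(ddof=1) > 0:
            standardized[b] = (w - w.mean()) / w.std(ddof=1)
        else:
            standardized[b] = pd.Series(0.0, index=w.index)
        standardized[b].name = "standardized"
    return CompositeWeights(
        weights=weights, standardized=standardized, intercept=intercept
    )


def top_features(cw: CompositeWeights, fraction: float = 0.05) -> dict:
    """Per-block ranked lists of the most heavily weighted features.

    Keeps the ``ceil(fraction * n_features)`` features with the largest
    absolute standardized weight; a tie in |weight| at the boundary expands
    the list rather than truncating arbitrarily.  Returns
    ``{block: DataFrame(feature, weight, standardized, rank)}``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    out = {}
    for block, std in cw.standardized.items():
        n = len(std)
        if n == 0:
            out[block] = pd.DataFrame(
                columns=["feature", "weight", "standardized", "rank"]
            )
            continue
        k = math.ceil(fraction * n)
        absw = std.abs().sort_values(ascending=False, kind="stable")
        cut = absw.iloc[k - 1]
        chosen = absw.index[absw >= cut]  # boundary ties expand the list
        df = pd.DataFrame(
            {
                "feature": chosen,
                "weight": cw.weights[block].loc[chosen].to_numpy(),
                "standardized": std.loc[chosen].to_numpy(),
            }
        )
        df["rank"] = np.arange(1, len(df) + 1)
        out[block] = df.reset_index(drop=True)
    return out


def export_weights(cw: CompositeWeights, directory, fraction: float = 0.05) -> list:
    """Write per-block TSVs (feature, weight, standardized, rank over all
    features) plus plain-text top-feature lists and their pooled union.

    Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    tops = top_features(cw, fraction)
    union: list[str] = []
    for block, w in cw.weights.items():
        df = pd.DataFrame(
            {"feature": w.index, "weight": w.to_numpy(),
             "standardized": cw.standardized[block].to_numpy()}
        )
        df = df.reindex(
            df["standardized"].abs().sort_values(ascending=False, kind="stable").index
        )
        df["rank"] = np.arange(1, len(df) + 1)
        p = directory / f"{block}_weights.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
        lst = directory / f"{block}_top_features.txt"
        feats = tops[block]["feature"].tolist()
        lst.write_text("\n".join(feats) + "\n")
        written.append(lst)
        union.extend(f for f in feats if f not in union)
    up = directory / "union_top_features.txt"
    up.write_text("\n".join(union) + "\n")
    written.append(up)
    return written
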