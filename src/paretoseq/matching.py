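"""Collapse per-promoter ChIP signal to one value per gene, plus QC.

Because a gene can have several promoters, its ChIP signal must be reduced
to a single gene x sample value before it can be contrasted against gene
expression.  Two strategies are offered:

``highest``
    pick the single promoter with the largest abundance and use its full
    per-sample count vector.  One consistent promoter is chosen per gene
    (not a per-sample argmax), so a fold change on the matched signal
    reflects abundance change at one promoter rather than promoter
    switching.
``weighted.mean``
    the abundance-weighted mean over the gene's promoters, per sample.

"Abundance" for both selection and weighting is the promoter's mean raw
count across all samples of the mark — an across-sample statistic, so the
chosen promoter/weights are identical in both conditions.

Body-mode marks (H3K36me3) bypass matching: the gene-body counts are the
gene-level signal already.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .chip import RegionCounts
from .errors import ValidationError
from .rnaseq import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedSignal",
    "match_highest",
    "match_weighted_mean",
    "match_body",
    "match",
    "correlation_matrix",
]


@dataclass
class MatchedSignal:
    """Gene x sample ChIP signal for one mark after matching."""

    mark_name: str
    values: pd.DataFrame  # genes x samples, non-negative reals
    strategy_used: str

    def __post_init__(self) -> None:
        if self.strategy_used not in ("highest", "weighted.mean", "body"):
            raise ValueError(f"unknown strategy {self.strategy_used!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError(f"mark {self.mark_name}: negative matched values")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def _require_promoter(rc: RegionCounts, op: str) -> None:
    if not rc.is_promoter:
        raise ValidationError(
            f"{op} requires promoter-mode counts (gene_id, tss index); "
            f"mark {rc.mark_name} has body-mode counts"
        )


def match_highest(promoter_counts: RegionCounts) -> MatchedSignal:
    """Per gene, the promoter with the largest mean count across samples.

    The gene's row is an exact copy of that promoter's per-sample vector.
    Ties are broken by the smallest TSS coordinate.
    """
    _require_promoter(promoter_counts, "match_highest")
    df = promoter_counts.counts.sort_index()
    means = df.mean(axis=1)
    rows = {}
    for gene_id, sub in means.groupby(level="gene_id", sort=True):
        # idxmax on a MultiIndex slice honours index order, which is sorted
        # by (gene_id, tss) — first maximal mean has the smallest TSS
        best = sub.idxmax()
        rows[gene_id] = df.loc[best]
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return MatchedSignal(promoter_counts.mark_name, out.astype(float), "highest")


def match_weighted_mean(promoter_counts: RegionCounts) -> MatchedSignal:
    """Abundance-weighted mean over a gene's promoters, per sample.

    Weight of promoter p = its mean count across samples.  If every weight
    is zero the unweighted mean is used (all-zero promoters give 0).
    """
    _require_promoter(promoter_counts, "match_weighted_mean")
    df = promoter_counts.counts.sort_index()
    weights = df.mean(axis=1)
    rows = {}
    for gene_id, sub in df.groupby(level="gene_id", sort=True):
        w = weights.loc[sub.index].to_numpy()
        x = sub.to_numpy(dtype=float)
        if w.sum() > 0:
            rows[gene_id] = (w[:, None] * x).sum(axis=0) / w.sum()
        else:
            rows[gene_id] = x.mean(axis=0)
    out = pd.DataFrame(rows, index=df.columns).T
    out.index.name = "gene_id"
    return MatchedSignal(promoter_counts.mark_name, out, "weighted.mean")


def match_body(body_counts: RegionCounts) -> MatchedSignal:
    """Gene-body counts are already gene-level; wrap them unchanged."""
    if body_counts.is_promoter:
        raise ValidationError(
            f"match_body requires body-mode counts; mark {body_counts.mark_name} "
            "has promoter-mode counts"
        )
    return MatchedSignal(body_counts.mark_name, body_counts.counts.astype(float), "body")


def match(region_counts: RegionCounts, strategy: str = "highest") -> MatchedSignal:
    """Dispatch: body-mode counts pass through, promoter counts use ``strategy``."""
    if not region_counts.is_promoter:
        return match_body(region_counts)
    if strategy == "highest":
        return match_highest(region_counts)
    if strategy == "weighted.mean":
        return match_weighted_mean(region_counts)
    raise ValidationError(f"unknown matching strategy {strategy!r}")


def correlation_matrix(rna: CountMatrix, matched: list[MatchedSignal]) -> pd.DataFrame:
    """Spearman correlation of all samples across all layers, for QC.

    Samples are labelled ``RNA:<sample>`` and ``<mark>:<sample>``.  Values
    are log2(x+1)-transformed (rank correlation only sees this through tie
    structure) and correlated over the gene-id intersection of all layers.
    Constant columns yield NaN against every other sample (undefined, not
    0); the diagonal is 1 by convention.
    """
    layers: dict[str, pd.DataFrame] = {"RNA": rna.counts.astype(float)}
    for ms in matched:
        if ms.mark_name in layers:
            raise ValidationError(f"duplicate mark {ms.mark_name} in correlation input")
        layers[ms.mark_name] = ms.values

    shared = None
    for df in layers.values():
        idx = df.index
        shared = idx if shared is None else shared.intersection(idx)
    if shared is None or len(shared) < 3:
        raise ValidationError(
            f"correlation needs >= 3 genes shared across all layers, got "
            f"{0 if shared is None else len(shared)}"
        )
    shared = shared.sort_values()

    cols, labels = [], []
    for layer, df in layers.items():
        sub = df.loc[shared]
        for sample in sub.columns:
            labels.append(f"{layer}:{sample}")
            cols.append(np.log2(sub[sample].to_numpy(dtype=float) + 1.0))
    X = np.column_stack(cols)

    ranks = np.apply_along_axis(rankdata, 0, X)
    centered = ranks - ranks.mean(axis=0)
    sd = centered.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered.T @ centered) / len(shared) / np.outer(sd, sd)
    corr[:, sd == 0] = np.nan
    corr[sd == 0, :] = np.nan
    np.fill_diagonal(corr, 1.0)
    n_const = int((sd == 0).sum())
    if n_const:
        logger.warning("correlation_matrix: %d constant sample column(s) -> NaN entries", n_const)
    return pd.DataFrame(corr, index=labels, columns=labels)
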