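"""Normalization, per-gene log fold changes, shrinkage, and Z scores.

The two data layers (gene expression and matched ChIP signal) are put on a
common footing as per-gene (logFC, SE) pairs and then combined, per gene g
and mark h, into

    Z_{g,h} = (logFC_RNA_g / se_RNA_g) * (logFC_ChIP_{g,h} / se_ChIP_{g,h})

i.e. the product of the two standardized log2 fold changes.  Z is large and
positive when expression and mark change strongly in the same direction,
large and negative when they change in opposite directions, and near zero
when either change is weak or noisy.

The differential estimates deliberately use simple, transparent machinery:

* median-of-ratios size factors (the standard count normalization for
  sequencing depth and composition);
* a pseudocount-moderated log2 fold change of normalized condition means;
* a per-gene standard error from the per-condition variance of
  log2(normalized count + pseudocount), pooled Welch-style and floored;
* an optional empirical multiplicative shrinkage tau^2/(tau^2 + se^2) that
  attenuates noisy estimates toward zero without changing their sign.

Externally computed (logfc, se) tables — e.g. from a negative-binomial GLM
fit — can be imported with :func:`DiffResult.from_tsv` and used in place of
:func:`logfc_se`; the Z-score and Pareto stages only need (logfc, se).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rnaseq import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiffResult",
    "ZScoreTable",
    "size_factors",
    "logfc_se",
    "shrink_logfc",
    "z_scores",
]

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_SE_MIN = 0.05


@dataclass
class DiffResult:
    """Per-gene logFC (log2, condition B over A), its SE, and baseMean."""

    layer: str
    table: pd.DataFrame  # index gene; columns: baseMean, logfc, se

    def __post_init__(self) -> None:
        missing = {"baseMean", "logfc", "se"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"layer {self.layer}: missing column(s) {sorted(missing)}")
        if (self.table["se"] <= 0).any():
            raise ValidationError(f"layer {self.layer}: se must be strictly positive")
        if self.table.index.has_duplicates:
            raise ValidationError(f"layer {self.layer}: duplicated gene ids")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, layer: str) -> "DiffResult":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(layer=layer, table=df[["baseMean", "logfc", "se"]])


@dataclass
class ZScoreTable:
    """Gene x mark Z values plus each mark's transcriptional direction."""

    zscores: pd.DataFrame  # genes x marks, finite
    directions: dict[str, str]  # mark -> activating | repressive

    def __post_init__(self) -> None:
        if not np.isfinite(self.zscores.to_numpy(dtype=float)).all():
            raise ValidationError("Z-score table contains non-finite entries")
        missing = set(self.zscores.columns) - set(self.directions)
        if missing:
            raise ValidationError(f"marks without a direction: {sorted(missing)}")

    def to_tsv(self, path) -> None:
        self.zscores.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def size_factors(counts: CountMatrix, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factor per sample.

    The reference for gene g is the geometric mean of its counts across
    samples, computed over genes with strictly positive counts everywhere;
    the factor for sample s is the median over those genes of
    ``counts[g, s] / reference[g]``.

    With ``allow_pseudo_reference=True``, genes with at least one positive
    count contribute instead (geometric mean over their positive entries,
    ratios taken only where the sample count is positive) — for sparse data
    where no gene is positive everywhere.
    """
    mat = counts.counts.to_numpy(dtype=float)
    samples = counts.sample_ids
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        logs = np.log(sub)
        log_ratios = logs - logs.mean(axis=1)[:, None]
        # a gene with identical counts in every sample has ratio exactly 1;
        # enforce it so identical samples yield factors of exactly 1
        log_ratios[(sub == sub[:, :1]).all(axis=1)] = 0.0
        factors = np.median(np.exp(log_ratios), axis=0)
    elif allow_pseudo_reference:
        any_pos = (mat > 0).any(axis=1)
        if not any_pos.any():
            raise ValidationError("size_factors: all counts are zero")
        sub = mat[any_pos]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        reference = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / reference[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        raise ValidationError(
            "size_factors: no gene has positive counts in every sample; "
            "re-run with allow_pseudo_reference=True to use a positive-counts reference"
        )
    return pd.Series(factors, index=samples, name="size_factor")


def logfc_se(
    counts: CountMatrix,
    condition_a: str,
    condition_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    se_min: float = DEFAULT_SE_MIN,
    layer: str = "RNA",
    allow_pseudo_reference: bool = False,
) -> DiffResult:
    """Moderated log2 fold change (B over A) with a per-gene standard error.

    Counts are first divided by median-of-ratios size factors.  Then, with
    pc the pseudocount and n_{g,s} the normalized counts,

        logfc_g = log2( (mean_B n + pc) / (mean_A n + pc) )

    and se_g is the Welch-pooled standard error of the per-condition means
    of log2(n + pc), floored at ``se_min``.  With a single replicate in
    either condition no variance is estimable and se_g = se_min uniformly
    (logged prominently).  Genes with all-zero counts in both conditions
    are excluded.
    """
    a_samples = counts.samples_of(condition_a)
    b_samples = counts.samples_of(condition_b)
    if not a_samples or not b_samples:
        known = sorted(set(counts.condition.values()))
        raise ValidationError(
            f"conditions ({condition_a!r}, {condition_b!r}) must each have >= 1 sample; "
            f"labels present: {known}"
        )
    if pseudocount <= 0:
        raise ValidationError(f"pseudocount must be positive, got {pseudocount}")

    used = counts.counts[a_samples + b_samples]
    sf = size_factors(
        CountMatrix(used, {s: counts.condition[s] for s in used.columns}),
        allow_pseudo_reference=allow_pseudo_reference,
    )
    norm = used / sf

    keep = (norm.to_numpy() > 0).any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("logfc_se[%s]: excluded %d all-zero gene(s)", layer, n_drop)
    norm = norm.loc[keep]

    na, nb = norm[a_samples].to_numpy(), norm[b_samples].to_numpy()
    mean_a, mean_b = na.mean(axis=1), nb.mean(axis=1)
    logfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    if len(a_samples) < 2 or len(b_samples) < 2:
        logger.warning(
            "logfc_se[%s]: <= 1 replicate in a condition; no variance estimable, "
            "se set to the floor %g for every gene",
            layer,
            se_min,
        )
        se = np.full(len(norm), se_min)
    else:
        la = np.log2(na + pseudocount)
        lb = np.log2(nb + pseudocount)
        var_a = la.var(axis=1, ddof=1)
        var_b = lb.var(axis=1, ddof=1)
        se = np.sqrt(var_a / len(a_samples) + var_b / len(b_samples))
        se = np.maximum(se, se_min)

    table = pd.DataFrame(
        {"baseMean": norm.mean(axis=1), "logfc": logfc, "se": se}, index=norm.index
    )
    return DiffResult(layer=layer, table=table)


def shrink_logfc(diff: DiffResult, prior_scale="auto") -> DiffResult:
    """Empirical multiplicative shrinkage of logFC toward zero.

    shrunken logfc_g = logfc_g * tau^2 / (tau^2 + se_g^2), with the prior
    variance tau^2 = max(0, var(logfc) - mean(se^2)) estimated across genes
    when ``prior_scale='auto'``, else tau = prior_scale.  Estimates with
    large SE (few replicates, low counts, high dispersion) are pulled
    strongly toward 0; precise estimates are nearly untouched.  The SE
    column is left unchanged; shrinkage never flips a sign and, for equal
    SE, preserves the ordering of |logfc|.
    """
    logfc = diff.table["logfc"].to_numpy(dtype=float)
    se = diff.table["se"].to_numpy(dtype=float)
    if prior_scale == "auto":
        tau2 = max(0.0, float(np.var(logfc, ddof=1) - np.mean(se**2))) if len(logfc) > 1 else 0.0
    else:
        if prior_scale <= 0:
            raise ValidationError(f"prior_scale must be positive or 'auto', got {prior_scale}")
        tau2 = float(prior_scale) ** 2
    if tau2 == 0.0:
        warnings.warn(
            f"shrink_logfc[{diff.layer}]: estimated prior variance is 0; "
            "all logFC shrunk to 0",
            stacklevel=2,
        )
    shrunk = logfc * tau2 / (tau2 + se**2)
    table = diff.table.copy()
    table["logfc"] = shrunk
    return DiffResult(layer=diff.layer, table=table)


def z_scores(
    rna: DiffResult,
    chips: dict[str, DiffResult],
    directions: dict[str, str],
) -> ZScoreTable:
    """Combine RNA and per-mark ChIP (logfc, se) into the gene x mark Z table.

    Z_{g,h} = (rna.logfc_g / rna.se_g) * (chip_h.logfc_g / chip_h.se_g).
    Genes absent from any layer are dropped (logged).
    """
    if not chips:
        raise ValidationError("z_scores: no ChIP layers supplied")
    genes = rna.table.index
    for diff in chips.values():
        genes = genes.intersection(diff.table.index)
    if len(genes) == 0:
        raise ValidationError("z_scores: empty gene intersection across layers")
    n_drop = max(len(rna.table), *(len(d.table) for d in chips.values())) - len(genes)
    if n_drop:
        logger.info("z_scores: %d gene(s) missing from some layer were dropped", n_drop)
    genes = genes.sort_values()

    rna_t = rna.table.loc[genes]
    rna_std = rna_t["logfc"] / rna_t["se"]
    cols = {}
    for mark, diff in chips.items():
        sub = diff.table.loc[genes]
        cols[mark] = rna_std * (sub["logfc"] / sub["se"])
    zt = pd.DataFrame(cols, index=genes)
    return ZScoreTable(zscores=zt, directions={m: directions[m] for m in cols})
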