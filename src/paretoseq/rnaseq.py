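"""Transcript-level abundance input and gene-level count aggregation.

RNA-Seq quantification arrives as one tab-separated abundance file per
sample in the kallisto output layout (``target_id``, ``length``,
``eff_length``, ``est_counts``, ``tpm``).  Any quantifier producing the
same columns is accepted.  Estimated counts are real-valued; they are
summed over each gene's transcripts and rounded (half away from zero) only
at the gene level, so that downstream count models see integer counts
without accumulating per-transcript rounding error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptAbundance",
    "CountMatrix",
    "read_abundance",
    "read_tx2gene",
    "aggregate_to_genes",
]


@dataclass
class TranscriptAbundance:
    """Per-sample transcript quantification (est_counts, optional tpm)."""

    sample_id: str
    table: pd.DataFrame  # index: target_id; columns: est_counts [, tpm]

    def __post_init__(self) -> None:
        if "est_counts" not in self.table.columns:
            raise FormatError(f"sample {self.sample_id}: missing est_counts column")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"sample {self.sample_id}: duplicated target_id(s): {dups}")
        if (self.table["est_counts"] < 0).any():
            raise ValidationError(f"sample {self.sample_id}: negative est_counts")


@dataclass
class CountMatrix:
    """Feature x sample non-negative integer counts with condition labels.

    The shared currency of the RNA and ChIP differential stages.  When used
    for a two-condition contrast, ``condition`` must map every sample to one
    of exactly two labels.
    """

    counts: pd.DataFrame  # features x samples
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("count matrix contains negative entries")
        unknown = set(self.condition) - set(self.counts.columns)
        if unknown:
            raise ValidationError(f"condition labels for unknown samples: {sorted(unknown)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition.get(s) == label]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path, condition: Mapping[str, str] | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, dict(condition or {}))


def read_abundance(path, sample_id: str) -> TranscriptAbundance:
    """Read one kallisto-style abundance TSV for one sample.

    Requires ``target_id`` and ``est_counts`` columns; ``tpm`` is carried
    through when present.  Counts stay real-valued here — rounding happens
    only after aggregation to genes.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: could not read as TSV: {exc}") from exc
    missing = {"target_id", "est_counts"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s): {sorted(missing)}")
    keep = ["est_counts"] + (["tpm"] if "tpm" in df.columns else [])
    table = df.set_index("target_id")[keep]
    return TranscriptAbundance(sample_id=sample_id, table=table)


def read_tx2gene(path) -> dict[str, str]:
    """Read a 2-column TSV mapping transcript_id -> gene_id (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: tx2gene needs 2 columns (transcript_id, gene_id)")
    first = df.iloc[0]
    if first[0] in ("transcript_id", "target_id", "tx_id"):  # tolerate a header row
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def aggregate_to_genes(
    abundances: Iterable[TranscriptAbundance],
    tx2gene: Mapping[str, str],
    condition: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Sum transcript est_counts to gene level, round, and assemble a matrix.

    Transcripts absent from ``tx2gene`` are dropped (their number is
    logged).  Gene count = round-half-away-from-zero of the sum of
    est_counts over the gene's transcripts, per sample.
    """
    abundances = list(abundances)
    if not abundances:
        raise ValidationError("no abundance tables supplied")
    columns = {}
    n_dropped = 0
    for ab in abundances:
        est = ab.table["est_counts"]
        in_map = est.index.isin(tx2gene.keys())
        n_dropped += int((~in_map).sum())
        est = est[in_map]
        if est.empty:
            raise ValidationError(
                f"sample {ab.sample_id}: no transcript overlaps the tx2gene mapping"
            )
        gene_ids = est.index.map(tx2gene)
        sums = est.groupby(gene_ids).sum()
        columns[ab.sample_id] = pd.Series(
            _round_half_away_from_zero(sums.to_numpy()).astype(np.int64), index=sums.index
        )
    if n_dropped:
        logger.info("aggregate_to_genes: dropped %d transcript rows absent from tx2gene", n_dropped)
    mat = pd.DataFrame(columns).fillna(0).astype(np.int64)
    mat = mat.sort_index()
    mat.index.name = "gene_id"
    return CountMatrix(mat, dict(condition or {}))
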