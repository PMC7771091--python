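"""ChIP-Seq read counting over promoter windows and gene bodies.

A read contributes to every region its aligned span overlaps by at least
1 bp (half-open interval arithmetic, so a read ending exactly where a
region starts does not count).  Unmapped, secondary and supplementary
alignments are always excluded; a mapping-quality threshold and exclusion
of duplicate-flagged reads are optional.  Each mapped segment of a pair
counts once — no fragment reconstruction is attempted.

Counting is a single streaming pass over the alignment file with an
interval-tree lookup per read, so SAM input needs no index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import GenomicInterval, PromoterSet
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MarkSpec",
    "RegionCounts",
    "count_reads",
    "count_samples",
    "count_table_from_tsv",
    "promoter_regions",
]

ACTIVATING = "activating"
REPRESSIVE = "repressive"


@dataclass(frozen=True)
class MarkSpec:
    """A histone mark: its name, transcriptional direction, counting region.

    ``direction`` decides the sign with which the mark's Z scores enter the
    Pareto objectives (+1 activating, -1 repressive); ``region_mode``
    decides whether reads are counted over promoter windows or over the
    gene body (e.g. H3K36me3).
    """

    mark_name: str
    direction: str
    region_mode: str = "promoter"

    def __post_init__(self) -> None:
        if self.direction not in (ACTIVATING, REPRESSIVE):
            raise ValueError(
                f"mark {self.mark_name}: direction must be 'activating' or 'repressive'"
            )
        if self.region_mode not in ("promoter", "body"):
            raise ValueError(f"mark {self.mark_name}: region_mode must be 'promoter' or 'body'")


@dataclass
class RegionCounts:
    """Region x sample integer counts for one mark.

    For promoter-mode marks the index is a (gene_id, tss) MultiIndex; for
    body-mode marks it is a plain gene_id index.
    """

    mark_name: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size == 0:
            raise ValidationError(f"mark {self.mark_name}: empty count table")
        if not np.issubdtype(vals.dtype, np.number) or (vals < 0).any():
            raise ValidationError(f"mark {self.mark_name}: counts must be non-negative numbers")
        if np.any(vals != np.floor(vals)):
            raise ValidationError(f"mark {self.mark_name}: counts must be integers")
        if self.counts.index.has_duplicates:
            raise ValidationError(f"mark {self.mark_name}: duplicated region keys")

    @property
    def is_promoter(self) -> bool:
        return isinstance(self.counts.index, pd.MultiIndex)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        df = self.counts.reset_index()
        if self.is_promoter:
            df.columns = ["gene_id", "tss"] + list(self.counts.columns)
        else:
            df.columns = ["gene_id"] + list(self.counts.columns)
        df.to_csv(path, sep="\t", index=False)


def promoter_regions(promoters: PromoterSet) -> dict[tuple[str, int], GenomicInterval]:
    """Flatten a PromoterSet into (gene_id, tss) -> window for counting."""
    return {
        (gene_id, tss): win
        for gene_id, windows in promoters.items()
        for tss, win in windows
    }


def count_reads(
    alignment_path,
    regions: Mapping[Hashable, GenomicInterval],
    min_mapq: int = 0,
    exclude_duplicates: bool = False,
) -> dict[Hashable, int]:
    """Count reads overlapping each region in one SAM/BAM file.

    A read is counted for *every* region it overlaps by >= 1 bp; a read
    overlapping two overlapping promoter windows is counted in both.

    Chromosomes present in ``regions`` but absent from the alignment header
    yield zero counts with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    counts: dict[Hashable, int] = {key: 0 for key in regions}
    for key, win in regions.items():
        trees.setdefault(win.chrom, IntervalTree())[win.start : win.end] = key

    mode = "rb" if str(alignment_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignment_path), mode) as af:
        header_chroms = set(af.references)
        missing = set(trees) - header_chroms
        if missing:
            logger.warning(
                "%s: chromosomes %s present in regions but absent from alignment header; "
                "their regions get zero counts",
                alignment_path,
                sorted(missing),
            )
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if exclude_duplicates and read.is_duplicate:
                continue
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            for hit in tree.overlap(read.reference_start, read.reference_end):
                counts[hit.data] += 1
    return counts


def count_samples(
    mark: MarkSpec,
    sample_paths: Mapping[str, object],
    regions: Mapping[Hashable, GenomicInterval],
    min_mapq: int = 0,
    exclude_duplicates: bool = False,
) -> RegionCounts:
    """Count one mark's alignment files (sample -> path) into a RegionCounts."""
    cols = {
        sample: pd.Series(
            count_reads(path, regions, min_mapq=min_mapq, exclude_duplicates=exclude_duplicates)
        )
        for sample, path in sample_paths.items()
    }
    df = pd.DataFrame(cols).fillna(0).astype(np.int64)
    if regions and isinstance(next(iter(regions)), tuple):
        df.index = pd.MultiIndex.from_tuples(df.index, names=["gene_id", "tss"])
    else:
        df.index.name = "gene_id"
    df = df.sort_index()
    return RegionCounts(mark_name=mark.mark_name, counts=df)


def count_table_from_tsv(path, mark_name: str, region_mode: str = "promoter") -> RegionCounts:
    """Load a precomputed region x sample count table.

    Promoter tables carry ``gene_id`` and ``tss`` key columns, body tables
    only ``gene_id``; every remaining column is a sample.  Entries must be
    non-negative integers and region keys unique.
    """
    df = pd.read_csv(path, sep="\t")
    key_cols = ["gene_id", "tss"] if region_mode == "promoter" else ["gene_id"]
    missing = set(key_cols) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing key column(s) {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: empty count table")
    df = df.set_index(key_cols if len(key_cols) > 1 else key_cols[0])
    return RegionCounts(mark_name=mark_name, counts=df)
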