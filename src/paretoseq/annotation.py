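"""Gene models, promoter windows and gene bodies from GTF annotation.

Coordinate conventions
----------------------
GTF is 1-based with inclusive ends.  Every interval handled internally is
0-based half-open (``[start, end)``), the convention of BED and of SAM
alignment spans, so interval lengths are plain ``end - start`` and overlap
tests need no off-by-one corrections.

A gene usually has several transcripts and therefore several transcription
start sites (TSSs).  Each distinct TSS gets its own promoter window — a
fixed-width stretch centered on the TSS (default 5 kb) — and the matching
stage later decides how to collapse multi-promoter signal to one value per
gene.  The gene body is the genomic span from the gene's first to last
annotated position (not the exon union): body-associated marks such as
H3K36me3 are counted over this whole span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .errors import ConfigError, ParseError

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PromoterSet",
    "load_annotation",
    "derive_promoters",
    "gene_bodies",
    "promoters_to_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError(f"negative coordinates: [{self.start}, {self.end})")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class GeneModel:
    """One gene: strand, deduplicated TSS list, genomic body span.

    ``tss_list`` holds 1-based positions (one per distinct transcript start;
    transcripts sharing a start contribute a single entry).  ``body`` is the
    0-based half-open span from the gene's minimal start to maximal end over
    all its transcripts.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_list: list[int]
    body: GenomicInterval
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id}: empty TSS list")
        if len(set(self.tss_list)) != len(self.tss_list):
            raise ValueError(f"gene {self.gene_id}: duplicate TSS entries")
        for t in self.tss_list:
            if not (self.body.start < t <= self.body.end):
                # 1-based t lies within the body iff body.start < t <= body.end
                raise ValueError(f"gene {self.gene_id}: TSS {t} outside body {self.body}")


#: gene_id -> list of (tss, window) pairs, one window per distinct TSS
PromoterSet = dict[str, list[tuple[int, GenomicInterval]]]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def load_annotation(gtf_path) -> list[GeneModel]:
    """Parse a GTF file into one :class:`GeneModel` per ``gene_id``.

    Transcript extent is taken from ``transcript`` feature lines when
    present, otherwise from the min/max span of each transcript's ``exon``
    lines.  The TSS of a transcript is its start field on the '+' strand and
    its end field on the '-' strand (both 1-based).  The gene body spans
    min(start)..max(end) over all the gene's records.

    Raises
    ------
    ParseError
        On a line without 9 tab-separated columns, unparseable coordinates,
        or a transcript record lacking a ``gene_id`` attribute.  The message
        names the offending line number.
    """
    # per transcript: (gene_id, chrom, strand, min_start, max_end)
    tx: dict[str, list] = {}
    tx_has_record: dict[str, bool] = {}

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("transcript", "exon"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{gtf_path}: line {lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise ParseError(f"{gtf_path}: line {lineno}: invalid strand {strand!r}")
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            tx_id = attributes.get("transcript_id")
            if not gene_id:
                raise ParseError(f"{gtf_path}: line {lineno}: record without gene_id attribute")
            if not tx_id:
                raise ParseError(f"{gtf_path}: line {lineno}: record without transcript_id attribute")

            rec = tx.get(tx_id)
            if rec is None:
                tx[tx_id] = [gene_id, chrom, strand, start, end]
                tx_has_record[tx_id] = feature == "transcript"
            else:
                if rec[0] != gene_id or rec[1] != chrom or rec[2] != strand:
                    raise ParseError(
                        f"{gtf_path}: line {lineno}: transcript {tx_id} has inconsistent "
                        f"gene_id/chrom/strand across records"
                    )
                if feature == "transcript" and not tx_has_record[tx_id]:
                    # dedicated transcript line overrides exon-derived span
                    rec[3], rec[4] = start, end
                    tx_has_record[tx_id] = True
                elif feature == "transcript" or not tx_has_record[tx_id]:
                    rec[3] = min(rec[3], start)
                    rec[4] = max(rec[4], end)

    genes: dict[str, dict] = {}
    for tx_id, (gene_id, chrom, strand, start, end) in tx.items():
        g = genes.setdefault(
            gene_id, {"chrom": chrom, "strand": strand, "tss": set(), "lo": start, "hi": end, "tx": []}
        )
        if g["chrom"] != chrom or g["strand"] != strand:
            raise ParseError(f"gene {gene_id}: transcripts on different chromosomes or strands")
        g["tss"].add(start if strand == "+" else end)
        g["lo"] = min(g["lo"], start)
        g["hi"] = max(g["hi"], end)
        g["tx"].append(tx_id)

    models = []
    for gene_id, g in genes.items():
        body = GenomicInterval(g["chrom"], g["lo"] - 1, g["hi"], g["strand"])
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=g["chrom"],
                strand=g["strand"],
                tss_list=sorted(g["tss"]),
                body=body,
                transcript_ids=sorted(g["tx"]),
            )
        )
    models.sort(key=lambda m: m.gene_id)
    return models


def derive_promoters(genes: Iterable[GeneModel], promoter_size: int = 5000) -> PromoterSet:
    """Symmetric promoter window of ``promoter_size`` bp centered on each TSS.

    For a 1-based TSS ``t`` the window is ``[t-1-size/2, t-1+size/2)`` in
    0-based half-open coordinates, clipped at position 0.  Overlapping
    windows of the same gene are kept separate: the *highest* matching
    strategy needs per-promoter values.
    """
    if promoter_size <= 0 or promoter_size % 2 != 0:
        raise ConfigError(f"promoter_size must be positive and even, got {promoter_size}")
    half = promoter_size // 2
    promoters: PromoterSet = {}
    for gene in genes:
        windows = []
        for t in gene.tss_list:
            center = t - 1
            start = max(0, center - half)
            end = center + half
            windows.append((t, GenomicInterval(gene.chrom, start, end, gene.strand)))
        promoters[gene.gene_id] = windows
    return promoters


def gene_bodies(genes: Iterable[GeneModel]) -> dict[str, GenomicInterval]:
    """Map each gene to its genomic body span (0-based half-open)."""
    return {gene.gene_id: gene.body for gene in genes}


def promoters_to_bed(promoters: PromoterSet, path) -> None:
    """Write promoter windows as BED6 for inspection in a genome browser."""
    with open(path, "w") as fh:
        for gene_id in sorted(promoters):
            for tss, win in promoters[gene_id]:
                fh.write(f"{win.chrom}\t{win.start}\t{win.end}\t{gene_id}:{tss}\t0\t{win.strand}\n")
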