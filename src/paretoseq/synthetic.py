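"""Self-contained synthetic two-condition RNA-Seq + ChIP-Seq experiments.

The generator emulates a replicated two-condition design (condition A vs
B) with negative-binomial gene and promoter counts and a small number of
*planted* genes whose expression and histone-mark changes are related in a
known way:

concordant-up
    expression up in B, activating marks up, repressive marks down —
    exactly the consistency the Z-score/Pareto machinery should reward.
concordant-down
    the mirror image (expression down, activating down, repressive up).
discordant
    expression up but activating marks down and repressive marks up — a
    consistency violation that should *not* be rewarded.
null
    no planted change in any layer.

Counts are NB with a common size (dispersion) parameter and per-feature
lognormal baseline means; planted effects multiply the condition-B mean by
2^(+-effect_size).  All outputs are in the standard formats the pipeline
consumes: GTF annotation, kallisto-style abundance TSVs (gene counts split
over the gene's transcripts), per-mark region-count TSVs and, on request,
minimal coordinate-sorted SAM files whose reads realize the target counts
(reads are placed entirely inside their window, so when windows are
disjoint, counting them back recovers the targets exactly).  Everything is
reproducible from the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, derive_promoters, gene_bodies
from .chip import MarkSpec, RegionCounts, promoter_regions, ACTIVATING, REPRESSIVE
from .errors import ValidationError
from .rnaseq import CountMatrix

__all__ = ["SimConfig", "SimResult", "DEFAULT_MARKS", "simulate_experiment"]

DEFAULT_MARKS = (
    MarkSpec("H3K4me3", ACTIVATING, "promoter"),
    MarkSpec("H3K27ac", ACTIVATING, "promoter"),
    MarkSpec("H3K36me3", ACTIVATING, "body"),
    MarkSpec("H3K27me3", REPRESSIVE, "promoter"),
)

CLASS_NULL = "null"
CLASS_UP = "concordant_up"
CLASS_DOWN = "concordant_down"
CLASS_DISCORDANT = "discordant"


@dataclass
class SimConfig:
    """Study design and distributional parameters of one simulated experiment.

    Defaults describe the reference condition set: 500 genes, 1-3 promoters
    each, 2 replicates per condition, 4 marks, NB dispersion (size) 10,
    lognormal baselines, planted |log2FC| of 2.0 for 10 genes per planted
    class.
    """

    n_genes: int = 500
    promoters_per_gene: tuple[int, int] = (1, 3)
    replicates: int = 2
    marks: tuple[MarkSpec, ...] = DEFAULT_MARKS
    dispersion: float = 10.0  # NB size parameter; larger = less overdispersed
    n_concordant_up: int = 10
    n_concordant_down: int = 10
    n_discordant: int = 10
    effect_size: float = 2.0  # planted |log2 fold change|
    seed: int = 0
    # genome geometry (single chromosome)
    chrom: str = "chr1"
    gene_length: int = 8000
    gene_spacing: int = 30000
    tss_spacing: int = 1500
    read_length: int = 50
    # lognormal baseline means: log-space mean / sd
    rna_meanlog: float = 5.0
    rna_sdlog: float = 1.0
    chip_meanlog: float = 4.5
    chip_sdlog: float = 0.8
    body_meanlog: float = 5.5

    def __post_init__(self) -> None:
        lo, hi = self.promoters_per_gene
        if not (1 <= lo <= hi):
            raise ValidationError(f"invalid promoters_per_gene range {self.promoters_per_gene}")
        if self.n_genes <= 0 or self.replicates <= 0 or self.dispersion <= 0:
            raise ValidationError("n_genes, replicates and dispersion must be positive")
        n_planted = self.n_concordant_up + self.n_concordant_down + self.n_discordant
        if min(self.n_concordant_up, self.n_concordant_down, self.n_discordant) < 0:
            raise ValidationError("planted class sizes must be non-negative")
        if n_planted > self.n_genes:
            raise ValidationError(
                f"planted classes ({n_planted} genes) exceed n_genes={self.n_genes}"
            )
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if (hi - 1) * self.tss_spacing >= self.gene_length:
            raise ValidationError("TSSs would fall outside the gene body")
        if self.gene_spacing < self.gene_length + 6000:
            raise ValidationError("gene_spacing too small: promoter windows would collide")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{cond}_{r + 1}" for cond in ("A", "B") for r in range(self.replicates)]

    @property
    def condition(self) -> dict[str, str]:
        return {s: s.split("_")[0] for s in self.sample_ids}


@dataclass
class SimResult:
    """In-memory bundle of one simulated experiment plus its ground truth."""

    config: SimConfig
    genes: list[GeneModel]
    rna_counts: CountMatrix  # true gene-level counts
    abundances: dict[str, pd.DataFrame]  # sample -> kallisto-style table
    region_counts: dict[str, RegionCounts]  # mark -> counts
    truth: pd.DataFrame  # gene_id-indexed: class, rna_direction, <mark>_direction
    tx2gene: dict[str, str]
    true_means: dict[str, pd.DataFrame] = field(default_factory=dict)
    chrom_length: int = 0

    @property
    def condition(self) -> dict[str, str]:
        return self.config.condition


def _class_of(i: int, cfg: SimConfig) -> str:
    if i < cfg.n_concordant_up:
        return CLASS_UP
    if i < cfg.n_concordant_up + cfg.n_concordant_down:
        return CLASS_DOWN
    if i < cfg.n_concordant_up + cfg.n_concordant_down + cfg.n_discordant:
        return CLASS_DISCORDANT
    return CLASS_NULL


def _rna_direction(cls: str) -> int:
    return {CLASS_UP: 1, CLASS_DOWN: -1, CLASS_DISCORDANT: 1, CLASS_NULL: 0}[cls]


def _mark_direction(cls: str, mark: MarkSpec) -> int:
    """Planted direction of a mark's signal, by gene class."""
    act = mark.direction == ACTIVATING
    if cls == CLASS_UP:
        return 1 if act else -1
    if cls == CLASS_DOWN:
        return -1 if act else 1
    if cls == CLASS_DISCORDANT:
        # expression goes up while every mark moves the inconsistent way
        return -1 if act else 1
    return 0


def _nb(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """NB draws parameterized by mean and size (var = mu + mu^2/size)."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size_param, p[pos])
    return out


def _condition_means(base: np.ndarray, direction: np.ndarray, cfg: SimConfig) -> dict:
    """Per-condition expected counts: B shifted by 2^(direction*effect)."""
    shift = np.exp2(direction * cfg.effect_size)
    return {"A": base, "B": base * shift}


def simulate_experiment(cfg: SimConfig, out_dir=None, write_sam: bool = False) -> SimResult:
    """Generate one experiment; optionally write all files under ``out_dir``.

    Files written: ``genes.gtf``, ``tx2gene.tsv``, ``truth.tsv``,
    ``design.tsv``, ``rna/<sample>.tsv`` abundance tables,
    ``chip/<mark>.counts.tsv`` region counts and, with ``write_sam=True``,
    one coordinate-sorted ``chip/<mark>.<sample>.sam`` per mark and sample.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_ids
    n = cfg.n_genes

    # --- gene models on a single chromosome --------------------------------
    gene_ids = [f"gene{i:04d}" for i in range(n)]
    classes = [_class_of(i, cfg) for i in range(n)]
    lo, hi = cfg.promoters_per_gene
    n_tss = rng.integers(lo, hi + 1, size=n)
    genes: list[GeneModel] = []
    tx2gene: dict[str, str] = {}
    for i, gid in enumerate(gene_ids):
        gstart = 10000 + i * cfg.gene_spacing  # 1-based
        gend = gstart + cfg.gene_length - 1
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss = [gstart + k * cfg.tss_spacing for k in range(n_tss[i])]
        else:
            tss = [gend - k * cfg.tss_spacing for k in range(n_tss[i])]
        tx_ids = [f"{gid}.t{k}" for k in range(n_tss[i])]
        for t in tx_ids:
            tx2gene[t] = gid
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=cfg.chrom,
                strand=strand,
                tss_list=sorted(tss),
                body=GenomicInterval(cfg.chrom, gstart - 1, gend, strand),
                transcript_ids=tx_ids,
            )
        )
    chrom_length = 10000 + n * cfg.gene_spacing + 10000

    # --- RNA layer ---------------------------------------------------------
    rna_base = rng.lognormal(cfg.rna_meanlog, cfg.rna_sdlog, size=n)
    rna_dir = np.array([_rna_direction(c) for c in classes])
    rna_mu = _condition_means(rna_base, rna_dir, cfg)
    rna_cols = {}
    true_rna = {}
    for s in samples:
        mu = rna_mu[cfg.condition[s]]
        rna_cols[s] = _nb(rng, mu, cfg.dispersion)
        true_rna[s] = mu
    rna_counts = CountMatrix(
        pd.DataFrame(rna_cols, index=pd.Index(gene_ids, name="gene_id")),
        dict(cfg.condition),
    )

    # split gene counts over transcripts (weights fixed per gene)
    tx_weights = {g.gene_id: rng.dirichlet(np.ones(len(g.transcript_ids))) for g in genes}
    abundances: dict[str, pd.DataFrame] = {}
    for s in samples:
        rows = []
        for g in genes:
            total = rna_counts.counts.at[g.gene_id, s]
            w = tx_weights[g.gene_id]
            for k, (t, wk) in enumerate(zip(g.transcript_ids, w)):
                length = cfg.gene_length - k * cfg.tss_spacing
                eff = max(length - 100, 1)
                rows.append((t, length, eff, total * wk))
        df = pd.DataFrame(rows, columns=["target_id", "length", "eff_length", "est_counts"])
        rate = df["est_counts"] / df["eff_length"]
        denom = rate.sum()
        df["tpm"] = 0.0 if denom == 0 else rate / denom * 1e6
        abundances[s] = df

    # --- ChIP layers -------------------------------------------------------
    promoters = derive_promoters(genes)
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}
    region_counts: dict[str, RegionCounts] = {}
    true_means: dict[str, pd.DataFrame] = {"RNA": pd.DataFrame(true_rna, index=gene_ids)}
    for mark in cfg.marks:
        mdir = np.array([_mark_direction(c, mark) for c in classes])
        if mark.region_mode == "promoter":
            keys = list(promoter_regions(promoters).keys())
            gene_of = np.array([gene_index[k[0]] for k in keys])
            base = rng.lognormal(cfg.chip_meanlog, cfg.chip_sdlog, size=len(keys))
            index = pd.MultiIndex.from_tuples(keys, names=["gene_id", "tss"])
        else:
            keys = gene_ids
            gene_of = np.arange(n)
            base = rng.lognormal(cfg.body_meanlog, cfg.chip_sdlog, size=n)
            index = pd.Index(gene_ids, name="gene_id")
        mu = _condition_means(base, mdir[gene_of], cfg)
        cols, tmeans = {}, {}
        for s in samples:
            m = mu[cfg.condition[s]]
            cols[s] = _nb(rng, m, cfg.dispersion)
            tmeans[s] = m
        region_counts[mark.mark_name] = RegionCounts(
            mark.mark_name, pd.DataFrame(cols, index=index).sort_index()
        )
        true_means[mark.mark_name] = pd.DataFrame(tmeans, index=index)

    truth = pd.DataFrame(
        {
            "class": classes,
            "rna_direction": rna_dir,
            **{
                f"{mark.mark_name}_direction": [_mark_direction(c, mark) for c in classes]
                for mark in cfg.marks
            },
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    result = SimResult(
        config=cfg,
        genes=genes,
        rna_counts=rna_counts,
        abundances=abundances,
        region_counts=region_counts,
        truth=truth,
        tx2gene=tx2gene,
        true_means=true_means,
        chrom_length=chrom_length,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), write_sam=write_sam, rng=rng)
    return result


# --------------------------------------------------------------------------
# file emission


def _write_bundle(res: SimResult, out_dir: Path, write_sam: bool, rng: np.random.Generator):
    cfg = res.config
    os.makedirs(out_dir / "rna", exist_ok=True)
    os.makedirs(out_dir / "chip", exist_ok=True)

    with open(out_dir / "genes.gtf", "w") as fh:
        for g in res.genes:
            gstart, gend = g.body.start + 1, g.body.end
            for k, t in enumerate(g.transcript_ids):
                if g.strand == "+":
                    start, end = sorted(g.tss_list)[k], gend
                else:
                    start, end = gstart, sorted(g.tss_list)[k]
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{t}";'
                fh.write(
                    f"{g.chrom}\tsim\ttranscript\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    with open(out_dir / "tx2gene.tsv", "w") as fh:
        for t, gid in res.tx2gene.items():
            fh.write(f"{t}\t{gid}\n")

    res.truth.to_csv(out_dir / "truth.tsv", sep="\t")

    with open(out_dir / "design.tsv", "w") as fh:
        fh.write("sample\tcondition\n")
        for s in cfg.sample_ids:
            fh.write(f"{s}\t{cfg.condition[s]}\n")

    for s, df in res.abundances.items():
        df.to_csv(out_dir / "rna" / f"{s}.tsv", sep="\t", index=False)

    promoters = derive_promoters(res.genes)
    prom_windows = promoter_regions(promoters)
    bodies = gene_bodies(res.genes)
    for mark in cfg.marks:
        rc = res.region_counts[mark.mark_name]
        rc.to_tsv(out_dir / "chip" / f"{mark.mark_name}.counts.tsv")
        if write_sam:
            windows = prom_windows if mark.region_mode == "promoter" else bodies
            for s in cfg.sample_ids:
                _write_sam(
                    out_dir / "chip" / f"{mark.mark_name}.{s}.sam",
                    rc.counts[s],
                    windows,
                    cfg,
                    res.chrom_length,
                    rng,
                )


def _write_sam(path, counts: pd.Series, windows, cfg: SimConfig, chrom_len: int, rng):
    """Minimal coordinate-sorted SAM realizing the per-region target counts.

    Reads are ungapped (``<read_length>M``) and placed uniformly so the
    whole read lies inside its window; when windows are disjoint, counting
    reads back per window reproduces the targets exactly.
    """
    starts = []
    for key, c in counts.items():
        win = windows[key]
        hi = win.end - cfg.read_length
        if hi <= win.start:
            raise ValidationError(f"window {key} shorter than read length")
        if c > 0:
            starts.append(rng.integers(win.start, hi + 1, size=int(c)))
    all_starts = np.sort(np.concatenate(starts)) if starts else np.array([], dtype=int)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{cfg.chrom}\tLN:{chrom_len}\n")
        for i, s0 in enumerate(all_starts):
            fh.write(
                f"r{i}\t0\t{cfg.chrom}\t{s0 + 1}\t60\t{cfg.read_length}M\t*\t0\t0\t*\t*\n"
            )
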