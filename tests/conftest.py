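import numpy as np
import pandas as pd
import pytest

from paretoseq.chip import RegionCounts
from paretoseq.integration import ZScoreTable
from paretoseq.synthetic import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete two-condition experiment with planted genes."""
    cfg = SimConfig(n_genes=60, seed=11)
    return simulate_experiment(cfg)


@pytest.fixture
def promoter_counts():
    """Hand-built promoter RegionCounts: two genes, three promoters, two samples."""
    index = pd.MultiIndex.from_tuples(
        [("gA", 100), ("gA", 900), ("gB", 5000)], names=["gene_id", "tss"]
    )
    df = pd.DataFrame({"s1": [10, 30, 7], "s2": [20, 40, 9]}, index=index)
    return RegionCounts("H3K4me3", df)


def make_ztable(values, directions=None, genes=None):
    """ZScoreTable from a plain array; all marks activating unless given."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:04d}" for i in range(arr.shape[0])]
    marks = [f"m{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=genes, columns=marks)
    directions = directions or {m: "activating" for m in marks}
    return ZScoreTable(df, directions)


@pytest.fixture
def ztable_factory():
    return make_ztable


def write_sam(path, reads, chrom="chr1", length=100000):
    """Write a minimal SAM file; reads = list of (name, flag, pos0, cigar, mapq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for name, flag, pos0, cigar, mapq in reads:
            fh.write(f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*\n")
    return path
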