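"""Read counting over regions and count-table validation."""

import numpy as np
import pandas as pd
import pytest

from paretoseq.annotation import GenomicInterval
from paretoseq.chip import MarkSpec, RegionCounts, count_reads, count_table_from_tsv
from paretoseq.errors import ValidationError

from conftest import write_sam


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestCountReads:
    def test_partial_overlap_counts(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 100, "50M", 60)])  # spans [100,150)
        counts = count_reads(sam, {"w": iv(140, 200)})
        assert counts["w"] == 1

    def test_half_open_boundary_read_excluded(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 100, "50M", 60)])
        counts = count_reads(sam, {"w": iv(150, 200)})
        assert counts["w"] == 0

    def test_read_in_two_overlapping_windows_counted_in_both(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 100, "50M", 60)])
        counts = count_reads(sam, {"w1": iv(90, 160), "w2": iv(120, 300)})
        assert counts == {"w1": 1, "w2": 1}

    def test_unmapped_secondary_supplementary_excluded(self, tmp_path):
        reads = [
            ("r1", 0, 100, "50M", 60),
            ("r2", 4, 100, "*", 0),  # unmapped
            ("r3", 256, 100, "50M", 60),  # secondary
            ("r4", 2048, 100, "50M", 60),  # supplementary
        ]
        sam = write_sam(tmp_path / "a.sam", reads)
        assert count_reads(sam, {"w": iv(90, 200)})["w"] == 1

    def test_min_mapq_monotone(self, tmp_path):
        reads = [(f"r{i}", 0, 100 + i, "50M", q) for i, q in enumerate([0, 10, 30, 60])]
        sam = write_sam(tmp_path / "a.sam", reads)
        regions = {"w": iv(0, 1000)}
        counts = [count_reads(sam, regions, min_mapq=q)["w"] for q in (0, 10, 30, 60, 61)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 4 and counts[-1] == 0

    def test_duplicate_flag_respected_only_on_request(self, tmp_path):
        reads = [("r1", 0, 100, "50M", 60), ("r2", 1024, 100, "50M", 60)]
        sam = write_sam(tmp_path / "a.sam", reads)
        regions = {"w": iv(0, 1000)}
        assert count_reads(sam, regions)["w"] == 2
        assert count_reads(sam, regions, exclude_duplicates=True)["w"] == 1

    def test_additive_over_file_concatenation(self, tmp_path):
        rng = np.random.default_rng(7)
        reads_a = [(f"a{i}", 0, int(p), "50M", 60) for i, p in enumerate(rng.integers(0, 900, 40))]
        reads_b = [(f"b{i}", 0, int(p), "50M", 60) for i, p in enumerate(rng.integers(0, 900, 25))]
        both = sorted(reads_a + reads_b, key=lambda r: r[2])
        sam_a = write_sam(tmp_path / "a.sam", sorted(reads_a, key=lambda r: r[2]))
        sam_b = write_sam(tmp_path / "b.sam", sorted(reads_b, key=lambda r: r[2]))
        sam_ab = write_sam(tmp_path / "ab.sam", both)
        regions = {"w1": iv(0, 300), "w2": iv(250, 600), "w3": iv(600, 950)}
        ca, cb, cab = (count_reads(s, regions) for s in (sam_a, sam_b, sam_ab))
        assert all(cab[k] == ca[k] + cb[k] for k in regions)

    def test_invariant_to_read_order(self, tmp_path):
        rng = np.random.default_rng(3)
        reads = [(f"r{i}", 0, int(p), "50M", 60) for i, p in enumerate(rng.integers(0, 900, 30))]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        regions = {"w": iv(100, 700)}
        c1 = count_reads(write_sam(tmp_path / "s1.sam", reads), regions)
        c2 = count_reads(write_sam(tmp_path / "s2.sam", shuffled), regions)
        assert c1 == c2

    def test_region_chromosome_missing_from_header(self, tmp_path, caplog):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 100, "50M", 60)])
        with caplog.at_level("WARNING"):
            counts = count_reads(sam, {"w": iv(0, 100, chrom="chrMissing")})
        assert counts["w"] == 0
        assert any("chrMissing" in rec.message for rec in caplog.records)


class TestCountTableFromTsv:
    def test_promoter_table_shape(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\ttss\ts1\ts2\ng1\t100\t5\t6\ng2\t200\t7\t8\n")
        rc = count_table_from_tsv(p, "H3K4me3", "promoter")
        assert rc.counts.shape == (2, 2)
        assert rc.is_promoter

    def test_duplicated_region_key_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\ttss\ts1\ng1\t100\t5\ng1\t100\t6\n")
        with pytest.raises(ValidationError, match="duplicated"):
            count_table_from_tsv(p, "H3K4me3", "promoter")

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\ttss\ts1\n")
        with pytest.raises(ValidationError, match="empty"):
            count_table_from_tsv(p, "H3K4me3", "promoter")

    @pytest.mark.parametrize("value", ["-3", "2.5"])
    def test_negative_or_fractional_entries_rejected(self, tmp_path, value):
        p = tmp_path / "c.tsv"
        p.write_text(f"gene_id\ts1\ng1\t{value}\n")
        with pytest.raises(ValidationError):
            count_table_from_tsv(p, "H3K36me3", "body")

    def test_round_trip_through_tsv(self, tmp_path, promoter_counts):
        out = tmp_path / "rt.tsv"
        promoter_counts.to_tsv(out)
        back = count_table_from_tsv(out, promoter_counts.mark_name, "promoter")
        pd.testing.assert_frame_equal(back.counts, promoter_counts.counts)


def test_markspec_enumerations_enforced():
    with pytest.raises(ValueError):
        MarkSpec("H3K4me3", "sideways")
    with pytest.raises(ValueError):
        MarkSpec("H3K4me3", "activating", "enhancer")
    assert MarkSpec("H3K36me3", "activating", "body").region_mode == "body"
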