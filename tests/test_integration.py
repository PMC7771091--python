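"""Size factors, logFC/SE estimation, shrinkage, and Z-score combination."""

import numpy as np
import pandas as pd
import pytest

from paretoseq.errors import ValidationError
from paretoseq.integration import (
    DiffResult,
    logfc_se,
    shrink_logfc,
    size_factors,
    z_scores,
)
from paretoseq.rnaseq import CountMatrix


def median_of_ratios_oracle(mat: np.ndarray) -> np.ndarray:
    """Independent literal implementation: geometric-mean reference over
    all-positive genes, per-sample median of count/reference ratios."""
    keep = [g for g in range(mat.shape[0]) if all(mat[g, s] > 0 for s in range(mat.shape[1]))]
    refs = {}
    for g in keep:
        prod = 1.0
        for s in range(mat.shape[1]):
            prod *= float(mat[g, s])
        refs[g] = prod ** (1.0 / mat.shape[1])
    factors = []
    for s in range(mat.shape[1]):
        ratios = sorted(mat[g, s] / refs[g] for g in keep)
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else 0.5 * (ratios[m // 2 - 1] + ratios[m // 2])
        factors.append(med)
    return np.array(factors)


def cm(data, condition=None, genes=None):
    df = pd.DataFrame(data)
    df.index = genes or [f"g{i}" for i in range(len(df))]
    return CountMatrix(df, condition or {})


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_symmetry(self):
        counts = cm({"s1": [10, 30], "s2": [20, 60]})
        f = size_factors(counts)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert f["s2"] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_identical_samples_give_unit_factors(self):
        counts = cm({"s1": [3, 11, 7], "s2": [3, 11, 7], "s3": [3, 11, 7]})
        assert (size_factors(counts) == 1.0).all()

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            mat = rng.integers(0, 200, size=(50, 4))
            mat[rng.random(size=mat.shape) < 0.1] = 0
            mat[:5] = rng.integers(1, 200, size=(5, 4))  # ensure all-positive genes exist
            counts = cm({f"s{j}": mat[:, j] for j in range(4)})
            expected = median_of_ratios_oracle(mat.astype(float))
            np.testing.assert_allclose(size_factors(counts).to_numpy(), expected, rtol=1e-12)

    def test_scaling_one_sample_scales_its_factor_ratio(self):
        # factors are defined up to a common scale: scaling sample s by c
        # multiplies the ratio factor_s/factor_t by c and leaves the ratios
        # between unscaled samples unchanged
        rng = np.random.default_rng(4)
        mat = rng.integers(1, 500, size=(60, 3)).astype(float)
        base = size_factors(cm({f"s{j}": mat[:, j] for j in range(3)}))
        scaled = mat.copy()
        scaled[:, 1] *= 3.0
        after = size_factors(cm({f"s{j}": scaled[:, j] for j in range(3)}))
        assert after["s1"] / after["s0"] == pytest.approx(3 * base["s1"] / base["s0"], rel=1e-9)
        assert after["s2"] / after["s0"] == pytest.approx(base["s2"] / base["s0"], rel=1e-9)

    def test_no_all_positive_gene_advises_fallback(self):
        counts = cm({"s1": [0, 5], "s2": [4, 0]})
        with pytest.raises(ValidationError, match="allow_pseudo_reference"):
            size_factors(counts)
        f = size_factors(counts, allow_pseudo_reference=True)
        assert (f > 0).all()


class TestLogfcSe:
    def _counts(self, a_mean, b_mean, n_other=20):
        """Target gene plus identical background so size factors are 1."""
        rng = np.random.default_rng(0)
        bg = rng.integers(10, 100, size=n_other)
        data = {}
        for s, mean in (("a1", a_mean), ("a2", a_mean), ("b1", b_mean), ("b2", b_mean)):
            data[s] = np.concatenate([[mean], bg])
        condition = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        return cm(data, condition)

    def test_logfc_formula_with_pseudocount(self):
        counts = self._counts(10, 40)
        diff = logfc_se(counts, "A", "B", pseudocount=0.5)
        assert diff.table.loc["g0", "logfc"] == pytest.approx(np.log2(40.5 / 10.5), abs=1e-9)

    def test_identical_conditions_give_zero_logfc(self):
        counts = self._counts(25, 25)
        diff = logfc_se(counts, "A", "B")
        assert np.allclose(diff.table["logfc"], 0.0)

    def test_condition_swap_negates_logfc(self):
        counts = self._counts(10, 40)
        fwd = logfc_se(counts, "A", "B")
        rev = logfc_se(counts, "B", "A")
        np.testing.assert_allclose(fwd.table["logfc"], -rev.table["logfc"], atol=1e-12)

    def test_all_zero_genes_excluded(self):
        counts = cm(
            {"a1": [0, 5, 12], "a2": [0, 6, 14], "b1": [0, 9, 11], "b2": [0, 7, 13]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        diff = logfc_se(counts, "A", "B")
        assert "g0" not in diff.table.index
        assert {"g1", "g2"} <= set(diff.table.index)

    def test_single_replicate_floors_all_se(self, caplog):
        counts = cm({"a1": [10, 30], "b1": [40, 50]}, {"a1": "A", "b1": "B"})
        with caplog.at_level("WARNING"):
            diff = logfc_se(counts, "A", "B", se_min=0.05)
        assert (diff.table["se"] == 0.05).all()
        assert any("replicate" in r.message for r in caplog.records)

    def test_unknown_condition_label_rejected(self):
        counts = self._counts(10, 40)
        with pytest.raises(ValidationError):
            logfc_se(counts, "A", "C")


class TestShrinkLogfc:
    def _diff(self, logfc, se):
        table = pd.DataFrame(
            {"baseMean": 10.0, "logfc": logfc, "se": se},
            index=[f"g{i}" for i in range(len(logfc))],
        )
        return DiffResult("RNA", table)

    def test_small_se_limit_recovers_original(self):
        diff = self._diff([2.0, -1.5], [1e-8, 1e-8])
        out = shrink_logfc(diff, prior_scale=1.0)
        np.testing.assert_allclose(out.table["logfc"], [2.0, -1.5], rtol=1e-9)

    def test_tau_equal_se_halves_logfc(self):
        diff = self._diff([2.0, -3.0], [0.7, 0.7])
        out = shrink_logfc(diff, prior_scale=0.7)
        np.testing.assert_allclose(out.table["logfc"], [1.0, -1.5], rtol=1e-12)

    def test_zero_logfc_is_fixed_point(self):
        diff = self._diff([0.0, 1.0], [0.3, 0.3])
        out = shrink_logfc(diff, prior_scale=2.0)
        assert out.table.loc["g0", "logfc"] == 0.0

    def test_never_increases_magnitude_or_flips_sign(self):
        rng = np.random.default_rng(8)
        logfc = rng.normal(0, 2, 40)
        se = rng.uniform(0.05, 1.5, 40)
        out = shrink_logfc(self._diff(logfc, se))
        assert (np.abs(out.table["logfc"]) <= np.abs(logfc) + 1e-12).all()
        assert (np.sign(out.table["logfc"]) * np.sign(logfc) >= 0).all()

    def test_degenerate_prior_warns_and_zeroes(self):
        # logfc variance below mean squared SE -> tau^2 estimated as 0
        diff = self._diff([0.01, -0.01, 0.02], [1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="prior variance"):
            out = shrink_logfc(diff, prior_scale="auto")
        assert (out.table["logfc"] == 0).all()

    def test_shrinkage_is_monotone_for_equal_se(self):
        logfc = np.array([0.2, 1.0, 2.5, -3.0, -0.5])
        out = shrink_logfc(self._diff(logfc, np.full(5, 0.4)), prior_scale=1.0)
        order_before = np.argsort(np.abs(logfc))
        order_after = np.argsort(np.abs(out.table["logfc"].to_numpy()))
        assert (order_before == order_after).all()


class TestZScores:
    def _diff(self, layer, logfc, se, genes=None):
        genes = genes or [f"g{i}" for i in range(len(logfc))]
        return DiffResult(
            layer, pd.DataFrame({"baseMean": 1.0, "logfc": logfc, "se": se}, index=genes)
        )

    def test_product_of_standardized_logfc(self):
        rna = self._diff("RNA", [1.0], [0.5])
        chipd = self._diff("H3K4me3", [-2.0], [1.0])
        zt = z_scores(rna, {"H3K4me3": chipd}, {"H3K4me3": "activating"})
        assert zt.zscores.loc["g0", "H3K4me3"] == pytest.approx(-4.0)

    def test_zero_logfc_in_either_layer_gives_zero(self):
        rna = self._diff("RNA", [0.0, 1.0], [0.5, 0.5])
        chipd = self._diff("H3K4me3", [3.0, 0.0], [1.0, 1.0])
        zt = z_scores(rna, {"H3K4me3": chipd}, {"H3K4me3": "activating"})
        assert (zt.zscores["H3K4me3"] == 0).all()

    def test_same_direction_changes_give_positive_z(self):
        rna = self._diff("RNA", [2.0, -2.0], [0.5, 0.5])
        chipd = self._diff("H3K4me3", [1.5, -1.5], [0.5, 0.5])
        zt = z_scores(rna, {"H3K4me3": chipd}, {"H3K4me3": "activating"})
        assert (zt.zscores["H3K4me3"] > 0).all()

    def test_genes_missing_from_a_layer_dropped(self):
        rna = self._diff("RNA", [1.0, 2.0], [0.5, 0.5], genes=["g0", "g1"])
        chipd = self._diff("H3K4me3", [1.0], [0.5], genes=["g1"])
        zt = z_scores(rna, {"H3K4me3": chipd}, {"H3K4me3": "activating"})
        assert list(zt.zscores.index) == ["g1"]

    def test_empty_intersection_rejected(self):
        rna = self._diff("RNA", [1.0], [0.5], genes=["g0"])
        chipd = self._diff("H3K4me3", [1.0], [0.5], genes=["gX"])
        with pytest.raises(ValidationError):
            z_scores(rna, {"H3K4me3": chipd}, {"H3K4me3": "activating"})

    def test_se_must_be_positive(self):
        with pytest.raises(ValidationError):
            self._diff("RNA", [1.0], [0.0])
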