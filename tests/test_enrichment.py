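"""Contingency tables, Fisher's exact test, bootstrap chi-square, log2FC summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from phylostage import (
    AgeMap,
    DegTable,
    ValidationError,
    chi2_bootstrap,
    fisher_exact,
    median_log2fc_by_stratum,
    naive_log2fc,
    stratum_contingency,
)


def fisher_p_oracle(a, b, c, d):
    """Independent brute force: enumerate all tables at the observed margins
    and sum hypergeometric probabilities <= the observed table's."""
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0  # the empty table is the only table
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = {k: hypergeom.pmf(k, n, col1, row1) for k in support}
    observed = pmf[a]
    return sum(p for p in pmf.values() if p <= observed * (1 + 1e-10))


class TestStratumContingency:
    def test_hand_count(self):
        background = AgeMap({"g1": 2, "g2": 2, "g3": 5})
        table = stratum_contingency({"g1"}, background, 2)
        assert table.tolist() == [[1, 0], [1, 1]]

    def test_empty_deg_list(self):
        background = AgeMap({"g1": 2, "g2": 2, "g3": 5})
        table = stratum_contingency(set(), background, 2)
        assert table.tolist() == [[0, 0], [2, 1]]

    def test_missing_gene_named(self):
        background = AgeMap({"g1": 2})
        with pytest.raises(ValidationError, match="ghost"):
            stratum_contingency({"ghost"}, background, 2)


class TestFisherExact:
    def test_diagonal_table(self):
        odds, p = fisher_exact([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 3)
        assert odds == np.inf

    def test_zero_margin_single_table(self):
        _, p = fisher_exact([[0, 0], [3, 5]])
        assert p == 1.0

    def test_symmetric_table(self):
        odds, p = fisher_exact([[1, 1], [1, 1]])
        assert odds == pytest.approx(1.0)
        assert p == 1.0

    def test_odds_ratio_nan_when_both_products_zero(self):
        odds, _ = fisher_exact([[0, 3], [0, 2]])
        assert np.isnan(odds)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[1, -1], [0, 2]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[1.5, 1], [1, 1]])

    @given(
        st.tuples(
            st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
        )
    )
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        _, p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_p_oracle(a, b, c, d), abs=1e-9)


def _uniform_background(n_per_stratum, n_strata):
    entries = {}
    for s in range(1, n_strata + 1):
        for k in range(n_per_stratum):
            entries[f"s{s}_g{k:03d}"] = s
    return AgeMap(entries)


class TestChi2Bootstrap:
    def test_proportional_composition_gives_p_one(self):
        background = _uniform_background(50, 2)
        deg = {f"s1_g{k:03d}" for k in range(10)} | {f"s2_g{k:03d}" for k in range(10)}
        result = chi2_bootstrap(deg, background, n_bootstrap=500, seed=1)
        assert result.chi2 == pytest.approx(0.0)
        assert result.bootstrap_p == 1.0

    def test_extreme_enrichment_small_p(self):
        background = _uniform_background(500, 2)
        deg = {f"s1_g{k:03d}" for k in range(50)}
        result = chi2_bootstrap(deg, background, n_bootstrap=10_000, seed=1)
        assert result.chi2 == pytest.approx(50.0)
        assert result.bootstrap_p <= 0.001

    def test_p_lower_bound_and_count_sums(self):
        background = _uniform_background(30, 4)
        deg = {f"s1_g{k:03d}" for k in range(12)}
        result = chi2_bootstrap(deg, background, n_bootstrap=200, seed=2)
        assert result.bootstrap_p >= 1 / 201
        assert result.per_stratum["count_deg"].sum() == len(deg)
        assert result.chi2_df == 3

    def test_bh_qvalues_monotone_in_sorted_p(self):
        background = _uniform_background(100, 6)
        rng = np.random.default_rng(7)
        deg = set(rng.choice(sorted(background.entries), size=60, replace=False))
        deg |= {f"s3_g{k:03d}" for k in range(40)}
        result = chi2_bootstrap(deg, background, n_bootstrap=200, seed=3)
        df = result.per_stratum.sort_values("fisher_p")
        assert (np.diff(df["fisher_q"]) >= -1e-12).all()
        assert (df["fisher_q"] >= df["fisher_p"] - 1e-12).all()

    def test_seed_reproducibility(self):
        background = _uniform_background(40, 5)
        deg = {f"s2_g{k:03d}" for k in range(15)}
        a = chi2_bootstrap(deg, background, n_bootstrap=300, seed=11)
        b = chi2_bootstrap(deg, background, n_bootstrap=300, seed=11)
        assert a.bootstrap_p == b.bootstrap_p
        pd.testing.assert_frame_equal(a.per_stratum, b.per_stratum)

    def test_deg_gene_absent_from_background_rejected(self):
        background = _uniform_background(5, 2)
        with pytest.raises(ValidationError, match="nope"):
            chi2_bootstrap({"nope"}, background, n_bootstrap=200, seed=0)


class TestMedianLog2fc:
    def _deg(self, rows):
        return DegTable(
            pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj", "stage", "cancer_type"])
        )

    def test_singleton_medians(self):
        ages = AgeMap({"a": 1, "b": 2})
        deg = self._deg([("a", 1.5, 0.01, "I", "X"), ("b", -0.5, 0.01, "I", "X")])
        table = median_log2fc_by_stratum(deg, ages)
        assert table.loc[1, "I"] == pytest.approx(1.5)
        assert table.loc[2, "I"] == pytest.approx(-0.5)

    def test_even_count_median(self):
        ages = AgeMap({"a": 3, "b": 3})
        deg = self._deg([("a", 1.0, 0.01, "II", "X"), ("b", 3.0, 0.01, "II", "X")])
        table = median_log2fc_by_stratum(deg, ages)
        assert table.loc[3, "II"] == pytest.approx(2.0)

    def test_absent_stratum_is_missing_not_zero(self):
        ages = AgeMap({"a": 1, "b": 5})
        deg = self._deg([("a", 1.0, 0.01, "I", "X")])
        table = median_log2fc_by_stratum(deg, ages)
        assert np.isnan(table.loc[5, "I"])
        assert np.isnan(table.loc[1, "III"])

    def test_missing_annotation_errors(self):
        ages = AgeMap({"a": 1})
        deg = self._deg([("zz", 1.0, 0.01, "I", "X")])
        with pytest.raises(ValidationError, match="zz"):
            median_log2fc_by_stratum(deg, ages)


class TestDegTable:
    def test_duplicate_within_stage_rejected(self):
        rows = [("a", 1.0, 0.01, "I", "X"), ("a", 2.0, 0.01, "I", "X")]
        with pytest.raises(ValidationError):
            DegTable(pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj", "stage", "cancer_type"]))

    def test_same_gene_distinct_stages_allowed(self):
        rows = [("a", 1.0, 0.01, "I", "X"), ("a", 2.0, 0.01, "II", "X")]
        table = DegTable(pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj", "stage", "cancer_type"]))
        assert len(table) == 2


class TestNaiveLog2fc:
    def test_hand_value(self):
        assert naive_log2fc([4.0], [1.0], pseudocount=1.0)[0] == pytest.approx(
            np.log2(5 / 2)
        )

    def test_identity_and_pseudocount_only(self):
        assert naive_log2fc([3.0], [3.0])[0] == 0.0
        assert naive_log2fc([0.0], [0.0], pseudocount=1.0)[0] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            naive_log2fc([1.0, 2.0], [1.0])

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            naive_log2fc([4.0], [1.0], pseudocount=0.0)
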