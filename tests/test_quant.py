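"""TPM and relative-abundance tests: arithmetic, invariants, category tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoclass.expression import ExpressionMatrix, sample_name
from thermoclass.quant import (
    RelativeAbundanceTable,
    category_distribution_tests,
    relative_abundance,
    tpm_no_length,
)


def matrix_from(values, genotypes=("A", "B"), temps=(25.0,), reps=(1,)):
    cols = [sample_name(g, t, r) for g in genotypes for t in temps for r in reps]
    df = pd.DataFrame(values, columns=cols[: np.shape(values)[1]],
                      index=[f"g{i}" for i in range(np.shape(values)[0])])
    return ExpressionMatrix(df)


class TestTPM:
    def test_direct_arithmetic(self):
        em = matrix_from([[1, 1], [1, 1], [2, 2]])
        tpm = tpm_no_length(em)
        np.testing.assert_allclose(tpm.values.iloc[:, 0], [250000, 250000, 500000])

    def test_equal_counts_give_equal_tpm(self):
        # no transcript-length term: identical counts map to identical TPM
        em = matrix_from([[5, 3], [5, 3], [10, 4]])
        tpm = tpm_no_length(em)
        pd.testing.assert_series_equal(
            tpm.values.iloc[0], tpm.values.iloc[1], check_names=False
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_columns_sum_to_million(self, seed):
        rng = np.random.default_rng(seed)
        em = matrix_from(rng.integers(0, 500, size=(30, 2)) + 1)
        tpm = tpm_no_length(em)
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_library_scaling_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(1, 100, size=(20, 2))
        a = tpm_no_length(matrix_from(y)).values
        b = tpm_no_length(matrix_from(y * 7)).values
        pd.testing.assert_frame_equal(a, b)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            tpm_no_length(matrix_from([[0, 1], [0, 1]]))

    def test_requires_counts(self, small_tpm):
        with pytest.raises(ValueError, match="raw counts"):
            tpm_no_length(small_tpm)


def four_genotype_tpm(rows, temps=(25.0,)):
    """rows: dict gene -> per-genotype mean TPM (2 identical replicates)."""
    genotypes = ("G1", "G2", "G3", "G4")
    cols = {}
    for g_i, g in enumerate(genotypes):
        for t in temps:
            for r in (1, 2):
                cols[sample_name(g, t, r)] = [rows[k][g_i] for k in rows]
    df = pd.DataFrame(cols, index=list(rows))
    return ExpressionMatrix(df, unit="tpm")


class TestRelativeAbundance:
    def test_equal_expression_gives_quarter_shares(self):
        tpm = four_genotype_tpm({"g1": [10, 10, 10, 10]})
        table = relative_abundance(tpm, 25.0)
        np.testing.assert_allclose(table.share.loc["g1"], 0.25)

    def test_direct_normalization(self):
        tpm = four_genotype_tpm({"g1": [10, 30, 40, 20]})
        table = relative_abundance(tpm, 25.0)
        np.testing.assert_allclose(table.share.loc["g1"], [0.1, 0.3, 0.4, 0.2])

    def test_single_genotype_expression(self):
        tpm = four_genotype_tpm({"g1": [0, 0, 7, 0]})
        table = relative_abundance(tpm, 25.0)
        np.testing.assert_allclose(table.share.loc["g1"], [0, 0, 1, 0])

    def test_unexpressed_genes_excluded(self):
        tpm = four_genotype_tpm({"g1": [1, 1, 1, 1], "g2": [0, 0, 0, 0]})
        table = relative_abundance(tpm, 25.0)
        assert list(table.excluded) == ["g2"]
        assert "g2" not in table.share.index

    def test_shares_sum_to_one(self, small_tpm):
        table = relative_abundance(small_tpm, 39.0)
        np.testing.assert_allclose(table.share.sum(axis=1), 1.0, rtol=1e-9)

    def test_display_rescaling_monotone_in_unit_interval(self, small_tpm):
        table = relative_abundance(small_tpm, 45.0)
        d = table.display.to_numpy()
        assert d.min() == pytest.approx(0.0) and d.max() == pytest.approx(1.0)
        # monotone: ranking per gene preserved
        x = table.share.to_numpy()
        assert (np.argsort(x, axis=1) == np.argsort(d, axis=1)).all()

    def test_permutation_equivariance(self):
        tpm = four_genotype_tpm({"g1": [10, 30, 40, 20], "g2": [5, 5, 5, 5]})
        table = relative_abundance(tpm, 25.0)
        perm = ["G3", "G1", "G4", "G2"]
        reordered = ExpressionMatrix(
            tpm.values[[c for g in perm for c in tpm.select_samples(genotype=g)]],
            unit="tpm",
        )
        table2 = relative_abundance(reordered, 25.0)
        pd.testing.assert_frame_equal(table.share[perm], table2.share)

    def test_missing_temperature_rejected(self, small_tpm):
        with pytest.raises(ValueError, match="absent"):
            relative_abundance(small_tpm, 60.0)


def share_table(X: pd.DataFrame) -> RelativeAbundanceTable:
    lo, hi = X.to_numpy().min(), X.to_numpy().max()
    disp = (X - lo) / (hi - lo) if hi > lo else X * 0.0
    return RelativeAbundanceTable(25.0, X * 100, X, disp, pd.Index([]))


class TestCategoryDistributionTests:
    def test_identical_shares_yield_p_one(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 0.4, size=50)
        X = pd.DataFrame(
            {g: vals for g in ("G1", "G2", "G3", "G4")},
            index=[f"g{i}" for i in range(50)],
        )
        cats = pd.Series("cat", index=X.index)
        report = category_distribution_tests(share_table(X), cats)
        assert report.loc[0, "pvalue"] == pytest.approx(1.0)
        assert not report.loc[0, "significant"]

    def test_shifted_genotype_detected(self):
        # one genotype's shares stochastically shifted by +0.2 (n=50 genes):
        # Kruskal-Wallis flags at p < 0.005 in at least 95% of 100 seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = rng.uniform(0.1, 0.3, size=(50, 4))
            base[:, 0] += 0.2
            X = pd.DataFrame(base, columns=["G1", "G2", "G3", "G4"],
                             index=[f"g{i}" for i in range(50)])
            cats = pd.Series("cat", index=X.index)
            report = category_distribution_tests(share_table(X), cats)
            hits += bool(report.loc[0, "significant"])
        assert hits >= 95

    def test_tukey_flags_match_separable_ordering(self):
        # three clearly separated genotype levels: every pair involving a
        # different level must be flagged, equal levels must not
        rng = np.random.default_rng(3)
        n = 40
        X = pd.DataFrame(
            {
                "G1": rng.normal(0.10, 0.005, n),
                "G2": rng.normal(0.10, 0.005, n),
                "G3": rng.normal(0.30, 0.005, n),
                "G4": rng.normal(0.50, 0.005, n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        cats = pd.Series("cat", index=X.index)
        report = category_distribution_tests(share_table(X), cats)
        pairs = set(report.loc[0, "significant_pairs"].split(";"))
        assert "G1|G2" not in pairs
        assert pairs == {"G1|G3", "G1|G4", "G2|G3", "G2|G4", "G3|G4"}

    def test_all_identical_category_rejected(self):
        X = pd.DataFrame(
            {g: [0.25] * 5 for g in ("G1", "G2", "G3", "G4")},
            index=[f"g{i}" for i in range(5)],
        )
        cats = pd.Series("cat", index=X.index)
        with pytest.raises(ValueError, match="all-identical"):
            category_distribution_tests(share_table(X), cats)

    def test_small_categories_skipped_and_anova_option(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(0.1, 0.4, size=(10, 4)),
                         columns=["G1", "G2", "G3", "G4"],
                         index=[f"g{i}" for i in range(10)])
        cats = pd.Series(["big"] * 8 + ["tiny"] * 2, index=X.index)
        report = category_distribution_tests(share_table(X), cats, method="anova")
        assert list(report["category"]) == ["big"]
        with pytest.raises(ValueError, match="method"):
            category_distribution_tests(share_table(X), cats, method="median")
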