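"""Genotype coding, HWE/independence tests and ANCOVA statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from inequifit.errors import DataError, InvalidInputError
from inequifit.genetics import (
    GenotypeCounts,
    add_derived_genotypes,
    ancova,
    carrier_334,
    classify_rs3_allele,
    crosstab_chisq,
    genotype_counts,
    genotype_report,
    hwe_chisq,
    pearson_corr,
    rs3_genotype,
)

# genotype counts as published for the three polymorphisms (n = 420)
OXTR_COUNTS = GenotypeCounts(171, 196, 53)
AVPR1A_COUNTS = GenotypeCounts(117, 203, 100)
OPRM1_COUNTS = GenotypeCounts(114, 201, 105)


class TestRs3Coding:
    @pytest.mark.parametrize(
        "length,expected", [(329, "S"), (330, "L"), (334, "L"), (310, "S")]
    )
    def test_median_split(self, length, expected):
        assert classify_rs3_allele(length) == expected

    @pytest.mark.parametrize(
        "a1,a2,expected",
        [(320, 340, "SL"), (340, 320, "SL"), (330, 330, "LL"), (310, 328, "SS")],
    )
    def test_genotype_order_insensitive(self, a1, a2, expected):
        assert rs3_genotype(a1, a2) == expected

    @pytest.mark.parametrize(
        "a1,a2,expected", [(334, 310, True), (310, 334, True), (330, 340, False)]
    )
    def test_carrier_flag(self, a1, a2, expected):
        assert carrier_334(a1, a2) is expected

    def test_rejects_nonpositive_length(self):
        with pytest.raises(InvalidInputError):
            classify_rs3_allele(0)

    def test_derived_columns(self):
        frame = pd.DataFrame(
            {"avpr1a_allele1_bp": [320, 334], "avpr1a_allele2_bp": [340, 310]}
        )
        out = add_derived_genotypes(frame)
        assert list(out["avpr1a_rs3"]) == ["SL", "SL"]
        assert list(out["carrier_334"]) == [False, True]


class TestHardyWeinberg:
    @pytest.mark.parametrize(
        "counts,expected_chi2",
        [
            (OXTR_COUNTS, 0.075),
            (AVPR1A_COUNTS, 0.423),
            (OPRM1_COUNTS, 0.756),
        ],
    )
    def test_reproduces_published_statistics(self, counts, expected_chi2):
        res = hwe_chisq(counts)
        assert res.df == 1
        assert round(res.chi2, 3) == pytest.approx(expected_chi2, abs=0.001)

    def test_exact_hwe_counts_score_zero(self):
        # p = 0.5: expected (n/4, n/2, n/4)
        res = hwe_chisq(GenotypeCounts(100, 200, 100))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_invariant_to_homozygote_relabelling(self):
        a = hwe_chisq(GenotypeCounts(171, 196, 53))
        b = hwe_chisq(GenotypeCounts(53, 196, 171))
        assert a.chi2 == pytest.approx(b.chi2)

    def test_monomorphic_sample_warns(self):
        with pytest.warns(UserWarning):
            res = hwe_chisq(GenotypeCounts(50, 0, 0))
        assert res.chi2 == 0.0

    def test_counts_from_series(self):
        values = ["AA"] * 3 + ["AG"] * 2 + ["GG"]
        assert genotype_counts(values, ("AA", "AG", "GG")) == (3, 2, 1)
        with pytest.raises(DataError):
            genotype_counts(["AA", "XX"], ("AA", "AG", "GG"))


class TestCrosstab:
    def test_independent_margins_score_zero(self):
        row = np.array([0.2, 0.5, 0.3])
        col = np.array([0.4, 0.4, 0.2])
        table = 1000 * np.outer(row, col)
        chi2, df, p = crosstab_chisq(table)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 4

    def test_matches_hand_computation(self):
        # 2x2-style block: observed vs expected worked out by hand
        table = np.array([[30, 10], [10, 30]])
        # margins 40/40, expected 20 in every cell -> chi2 = 4 * 100/20 = 20
        chi2, df, p = crosstab_chisq(table)
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        table = rng.integers(5, 50, size=(3, 3))
        base = crosstab_chisq(table)[0]
        for perm in itertools.permutations(range(3)):
            assert crosstab_chisq(table[list(perm)])[0] == pytest.approx(base)


def _synthetic_association_table(
    n=200, seed=0, rs3_effect=0.0, age_slope=0.0, noise=0.3
):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "oxtr": rng.choice(["AA", "AG", "GG"], n, p=[0.4, 0.47, 0.13]),
            "avpr1a_rs3": rng.choice(["SS", "SL", "LL"], n, p=[0.28, 0.48, 0.24]),
            "oprm1": rng.choice(["AA", "AG", "GG"], n, p=[0.27, 0.48, 0.25]),
            "age": rng.normal(41, 10, n),
            "sex": rng.choice(["female", "male"], n),
        }
    )
    l_count = frame["avpr1a_rs3"].map({"SS": 0, "SL": 1, "LL": 2})
    frame["dep"] = (
        0.4
        + rs3_effect * l_count
        + age_slope * (frame["age"] - 41)
        + rng.normal(0, noise, n)
    )
    return frame


def _oracle_design(data, factors, covariates):
    """Independent sum-coded design built with pandas dummies."""
    cols = [np.ones(len(data))]
    for f in factors:
        d = pd.get_dummies(data[f].astype(str)).astype(float)
        levels = sorted(d.columns)
        for lev in levels[:-1]:
            cols.append((d[lev] - d[levels[-1]]).to_numpy())
    for c in covariates:
        v = data[c].astype(float)
        cols.append((v - v.mean()).to_numpy())
    return np.column_stack(cols)


def _oracle_f_test(X, y, block):
    """RSS-comparison F test for dropping a column block (normal equations)."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rss_full = float(((y - X @ beta) ** 2).sum())
    keep = [j for j in range(X.shape[1]) if j not in block]
    Xr = X[:, keep]
    beta_r = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
    rss_red = float(((y - Xr @ beta_r) ** 2).sum())
    df_den = X.shape[0] - X.shape[1]
    q = len(block)
    return ((rss_red - rss_full) / q) / (rss_full / df_den)


def _oracle_t(X, y, c):
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    df_den = X.shape[0] - X.shape[1]
    mse = float(((y - X @ beta) ** 2).sum()) / df_den
    var = mse * float(c @ np.linalg.solve(X.T @ X, c))
    return float(c @ beta) / np.sqrt(var)


class TestAncova:
    FACTORS = ("oxtr", "avpr1a_rs3", "oprm1")

    def test_constant_dependent_gives_zero_f(self):
        frame = _synthetic_association_table(n=120, seed=1)
        frame["dep"] = 1.7
        res = ancova(frame, "dep", factors=self.FACTORS)
        for ft in res.factor_tests:
            assert ft.F == pytest.approx(0.0, abs=1e-12)
            assert ft.partial_eta2 == pytest.approx(0.0, abs=1e-12)

    def test_degrees_of_freedom_bookkeeping(self):
        frame = _synthetic_association_table(n=420, seed=2)
        res = ancova(frame, "dep", factors=self.FACTORS)
        # n - 1 (intercept) - 6 (three 3-level factors) - 1 (age) = 412
        assert res.df_den == 412
        for ft in res.factor_tests:
            assert ft.df_num == 2
            assert 0 <= ft.partial_eta2 <= 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_f_matches_normal_equations_oracle(self, seed):
        frame = _synthetic_association_table(n=60, seed=seed, rs3_effect=0.15)
        res = ancova(frame, "dep", factors=self.FACTORS)
        X = _oracle_design(frame, self.FACTORS, ("age",))
        y = frame["dep"].to_numpy()
        # column blocks in construction order: oxtr 1:3, avpr 3:5, oprm 5:7
        blocks = {"oxtr": [1, 2], "avpr1a_rs3": [3, 4], "oprm1": [5, 6]}
        for name, block in blocks.items():
            assert res.factor(name).F == pytest.approx(
                _oracle_f_test(X, y, block), abs=1e-8, rel=1e-8
            )

    @pytest.mark.parametrize("seed", [3, 4])
    def test_contrasts_match_normal_equations_oracle(self, seed):
        frame = _synthetic_association_table(n=30, seed=seed, rs3_effect=0.2)
        res = ancova(frame, "dep", factors=self.FACTORS)
        X = _oracle_design(frame, self.FACTORS, ("age",))
        y = frame["dep"].to_numpy()
        # avpr1a_rs3 columns 3 (LL - SS) and 4 (SL - SS), levels sorted
        codes = {"LL": np.array([1.0, 0.0]), "SL": np.array([0.0, 1.0]),
                 "SS": np.array([-1.0, -1.0])}
        for con in res.contrasts_frame().itertuples():
            if con.factor != "avpr1a_rs3":
                continue
            c = np.zeros(X.shape[1])
            c[3:5] = codes[con.level_a] - codes[con.level_b]
            assert con.t == pytest.approx(_oracle_t(X, y, c), abs=1e-8, rel=1e-8)

    def test_injected_effect_is_detected_with_sensible_effect_size(self):
        frame = _synthetic_association_table(n=420, seed=5, rs3_effect=-0.12)
        res = ancova(frame, "dep", factors=self.FACTORS)
        ft = res.factor("avpr1a_rs3")
        assert ft.p < 0.01
        assert ft.partial_eta2 > 0.01
        assert res.factor("oxtr").p > 0.05

    def test_median_f_monotone_in_effect_size(self):
        medians = []
        for effect in (0.0, 0.1, 0.2):
            fs = []
            for rep in range(30):
                frame = _synthetic_association_table(
                    n=100, seed=1000 + rep, rs3_effect=effect
                )
                fs.append(ancova(frame, "dep", factors=self.FACTORS).factor("avpr1a_rs3").F)
            medians.append(np.median(fs))
        assert medians[0] <= medians[1] <= medians[2]

    def test_bonferroni_threshold_is_017(self):
        frame = _synthetic_association_table(n=90, seed=6)
        res = ancova(frame, "dep", factors=self.FACTORS)
        assert res.contrasts
        assert all(c.bonferroni_threshold == 0.017 for c in res.contrasts)

    def test_identical_groups_give_zero_contrast(self):
        frame = _synthetic_association_table(n=90, seed=7)
        frame["dep"] = 2.0
        res = ancova(frame, "dep", factors=self.FACTORS)
        for c in res.contrasts:
            assert c.t == pytest.approx(0.0, abs=1e-10)
            assert c.cohen_d == pytest.approx(0.0, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        """With no genotype effect, factor p-values across replicates should
        be uniform on [0, 1] (Kolmogorov–Smirnov)."""
        from scipy import stats as ss

        p_values = []
        for rep in range(200):
            frame = _synthetic_association_table(n=80, seed=5000 + rep)
            res = ancova(frame, "dep", factors=self.FACTORS)
            p_values.extend(ft.p for ft in res.factor_tests)
        ks = ss.kstest(p_values, "uniform")
        assert ks.pvalue > 0.01, ks

    def test_carrier_coding_uses_two_level_factor(self):
        frame = _synthetic_association_table(n=120, seed=11)
        # independent stream: reusing the table's seed would replay the same
        # uniforms that generated the genotype columns and alias the factors
        rng = np.random.default_rng(999)
        frame["carrier_334"] = rng.random(len(frame)) < 0.37
        res = ancova(frame, "dep", factors=("oxtr", "carrier_334", "oprm1"))
        ft = res.factor("carrier_334")
        assert ft.df_num == 1
        assert ft.df_den == len(frame) - 1 - 5 - 1  # intercept, 2+1+2 codes, age

    def test_sex_interaction_terms_are_reported(self):
        frame = _synthetic_association_table(n=200, seed=8)
        res = ancova(frame, "dep", factors=self.FACTORS, sex_interactions=True)
        names = {ft.factor for ft in res.factor_tests}
        assert {"sex", "sex:oxtr", "sex:avpr1a_rs3", "sex:oprm1"} <= names

    def test_rank_deficiency_names_aliased_columns(self):
        frame = _synthetic_association_table(n=60, seed=9)
        frame["oxtr_copy"] = frame["oxtr"]
        with pytest.raises(InvalidInputError, match="rank deficient"):
            ancova(frame, "dep", factors=("oxtr", "oxtr_copy"))

    def test_single_level_factor_rejected(self):
        frame = _synthetic_association_table(n=60, seed=10)
        frame["oxtr"] = "AA"
        with pytest.raises(InvalidInputError):
            ancova(frame, "dep", factors=self.FACTORS)


class TestPearson:
    def test_perfect_correlation(self):
        u = np.arange(10.0)
        r, df, p = pearson_corr(u, u)
        assert r == pytest.approx(1.0)
        assert df == 8

    def test_hand_computed_five_points(self):
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # by hand: cov = 2, sd_u = sd_v = sqrt(2.5) -> r = 0.8
        r, df, p = pearson_corr(u, v)
        assert r == pytest.approx(0.8)
        assert df == 3

    def test_requires_three_points(self):
        with pytest.raises(InvalidInputError):
            pearson_corr([1, 2], [3, 4])


class TestGenotypeReport:
    def test_reproduces_published_distribution(self, published_genotype_table):
        rep = genotype_report(published_genotype_table)
        assert rep["n"] == 420
        oxtr = rep["genes"]["oxtr"]
        assert oxtr["counts"] == [171, 196, 53]
        assert oxtr["percent"] == [40.7, 46.7, 12.6]
        assert round(oxtr["hwe_chi2"], 3) == 0.075
        avpr = rep["genes"]["avpr1a_rs3"]
        assert avpr["counts"] == [117, 203, 100]
        assert avpr["percent"] == [27.9, 48.3, 23.8]
        assert round(avpr["hwe_chi2"], 3) == 0.423
        oprm = rep["genes"]["oprm1"]
        assert oprm["counts"] == [114, 201, 105]
        assert oprm["percent"] == [27.1, 47.9, 25.0]
        assert round(oprm["hwe_chi2"], 3) == 0.756
        assert rep["carrier_334"]["carriers"] == 154
        assert rep["carrier_334"]["percent"] == 36.7
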