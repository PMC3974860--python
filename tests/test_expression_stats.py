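"""Specificity scoring, correlation structure, strand and KD comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon
from scipy.stats import rankdata

from pseudoshadow import expression_stats as es
from pseudoshadow import synthetic_data as sd
from pseudoshadow.models import ExpressionMatrix, Feature


def js_oracle(profile: np.ndarray) -> float:
    """Independent JS score via scipy's jensenshannon (base-2 distance)."""
    p = np.asarray(profile, dtype=float)
    p = p / p.sum()
    best = -1.0
    for t in range(len(p)):
        e = np.zeros(len(p))
        e[t] = 1.0
        best = max(best, 1.0 - jensenshannon(p, e, base=2))
    return best


class TestJsSpecificity:
    def test_one_hot_scores_exactly_one(self):
        v = np.zeros(16)
        v[3] = 7.5
        res = es.js_specificity(v)
        assert res.score == pytest.approx(1.0, abs=1e-12)
        assert res.argmax_tissue == "3"

    def test_uniform_matches_independent_oracle(self):
        v = np.ones(16)
        assert es.js_specificity(v).score == pytest.approx(
            js_oracle(v), abs=1e-9)

    def test_random_profiles_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            v = rng.gamma(0.5, size=16) + 1e-9
            assert es.js_specificity(v).score == pytest.approx(
                js_oracle(v), abs=1e-9)

    @given(st.integers(0, 2**32 - 1), st.floats(0.01, 1000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance(self, seed, scale):
        v = np.random.default_rng(seed).gamma(1.0, size=8) + 1e-9
        assert es.js_specificity(v * scale).score == pytest.approx(
            es.js_specificity(v).score, abs=1e-12)

    def test_two_tissue_family_is_monotone_in_spread(self):
        scores = [es.js_specificity(np.array([1 - a, a])).score
                  for a in np.linspace(0.0, 0.5, 11)]
        assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]))

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            es.js_specificity(np.zeros(16))

    def test_table_flags_zero_rows_instead_of_scoring(self):
        fpkm = pd.DataFrame({"t1": [1.0, 0.0], "t2": [0.0, 0.0]},
                            index=["a", "z"])
        table = es.js_specificity_table(ExpressionMatrix(fpkm))
        assert table.loc["a", "defined"]
        assert not table.loc["z", "defined"]
        assert np.isnan(table.loc["z", "js_score"])


class TestMatchedControl:
    def test_same_seed_reproduces_sample(self):
        rng = np.random.default_rng(0)
        pg = pd.Series(rng.lognormal(1, 1, 50),
                       index=[f"pg{i}" for i in range(50)])
        pool = pd.Series(rng.lognormal(1, 1, 500),
                         index=[f"g{i}" for i in range(500)])
        s1 = es.expression_matched_control(pg, pool, seed=5)
        s2 = es.expression_matched_control(pg, pool, seed=5)
        assert s1.equals(s2)

    def test_matched_gene_comes_from_same_bin(self):
        pg = pd.Series({"pg0": 4.0})
        pool = pd.Series({"lo": 0.1, "match": 4.2, "hi": 400.0})
        got = es.expression_matched_control(pg, pool, seed=1)
        assert got["pg0"] == "match"

    def test_empty_bin_falls_back_with_warning(self):
        pg = pd.Series({"pg0": 1000.0})
        pool = pd.Series({"only": 1.0})
        with pytest.warns(UserWarning, match="empty"):
            got = es.expression_matched_control(pg, pool, seed=1)
        assert got["pg0"] == "only"

    def test_matched_distribution_passes_ks(self):
        rng = np.random.default_rng(7)
        vals = rng.lognormal(2, 1.5, 500)
        pg = pd.Series(vals, index=[f"pg{i}" for i in range(500)])
        pool = pd.Series(np.concatenate([vals, rng.lognormal(2, 1.5, 4500)]),
                         index=[f"g{i}" for i in range(5000)])
        matched = es.expression_matched_control(pg, pool, seed=2)
        from scipy.stats import ks_2samp
        p = ks_2samp(pg.to_numpy(), pool[matched].to_numpy()).pvalue
        assert p > 0.05


def spearman_oracle(x, y):
    """Tie-corrected rank correlation via the Pearson-of-ranks identity."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    def _matrix(self, rows, ids):
        df = pd.DataFrame(rows, index=ids,
                          columns=[f"t{i}" for i in range(len(rows[0]))])
        return ExpressionMatrix(df)

    def test_identical_and_reversed_profiles(self):
        x = np.arange(16, dtype=float) + 1
        pg = self._matrix([x, x], ["p1", "p2"])
        parent = self._matrix([x, x[::-1]], ["g1", "g2"])
        recs = es.pg_parent_spearman(pg, parent, [("p1", "g1"), ("p2", "g2")])
        assert recs[0].rho == pytest.approx(1.0)
        assert recs[1].rho == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_formula_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.integers(0, 5, 16).astype(float)  # heavy ties
            y = rng.integers(0, 5, 16).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            pg = self._matrix([x], ["p"])
            parent = self._matrix([y], ["g"])
            rec = es.pg_parent_spearman(pg, parent, [("p", "g")])[0]
            assert rec.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_all_zero_parent_excluded(self):
        pg = self._matrix([np.arange(16.0) + 1], ["p"])
        parent = self._matrix([np.zeros(16)], ["g"])
        assert es.pg_parent_spearman(pg, parent, [("p", "g")]) == []

    def test_exact_permutation_p_for_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pg = self._matrix([x], ["p"])
        parent = self._matrix([x], ["g"])
        rec = es.pg_parent_spearman(pg, parent, [("p", "g")])[0]
        # perfect monotone agreement: 2 of 5! orderings reach |rho|=1
        assert rec.p == pytest.approx(2 / 120)

    def test_too_few_tissues_rejected(self):
        pg = self._matrix([[1.0, 2.0]], ["p"])
        parent = self._matrix([[1.0, 2.0]], ["g"])
        with pytest.raises(ValueError):
            es.pg_parent_spearman(pg, parent, [("p", "g")])


class TestDistanceGroups:
    def _pg(self, start, end):
        return Feature("pg", "chr1", start, end, "+", "processed_pg",
                       ((start, end),), "g")

    @pytest.mark.parametrize("gap,expected", [
        (15_000, "t1"), (25_000, "t2"), (20_000, "t1"), (0, "t1"),
    ])
    def test_cutoff_rule(self, gap, expected):
        gene = Feature("g", "chr1", 0, 1000, "+", "gene", ((0, 1000),))
        pg = self._pg(1000 + gap, 2000 + gap)
        labels = es.distance_groups([pg], [gene])
        assert labels["pg"] == expected

    def test_overlap_counts_as_zero_distance(self):
        gene = Feature("g", "chr1", 0, 1000, "+", "gene", ((0, 1000),))
        pg = self._pg(500, 1500)
        assert es.distance_groups([pg], [gene])["pg"] == "t1"


class TestTissueSplit:
    def test_constant_parent_gives_zero_deltas(self):
        s = es.tissue_split_mean_variance(np.arange(16.0), np.full(16, 3.0))
        assert s.delta_mu == 0 and s.delta_s == 0

    def test_monotone_profiles_give_expected_mean_difference(self):
        x = np.arange(1.0, 17.0)
        s = es.tissue_split_mean_variance(x, x)
        assert s.delta_mu == pytest.approx(12.5 - 4.5)

    def test_odd_tissue_count_rejected(self):
        with pytest.raises(ValueError):
            es.tissue_split_mean_variance(np.ones(15), np.ones(15))

    def test_negative_rho_pairs_give_negative_delta_mu(self):
        pg, parent, _ = sd.simulate_expression_profiles(
            200, planted_rho=(-0.9,), seed=11)
        neg = sum(
            es.tissue_split_mean_variance(
                pg.fpkm.iloc[k].to_numpy(), parent.fpkm.iloc[k].to_numpy()
            ).delta_mu < 0
            for k in range(200)
        )
        assert neg > 0.9 * 200


class TestStrandRule:
    @pytest.mark.parametrize("sense,anti,expected", [
        (1.0, 0.05, "sense"),      # 20x >= 10x
        (0.5, 0.1, "both"),        # 5x < 10x
        (0.0, 0.3, "antisense"),
        (0.0, 0.0, "no_call"),
        (1.0, 0.1, "sense"),       # exactly 10x counts as dominant
        (0.3, 0.0, "sense"),       # zero lesser strand dominated
    ])
    def test_truth_table(self, sense, anti, expected):
        assert es.infer_strand(sense, anti) == expected

    def test_min_expr_cutoff_suppresses_weak_calls(self):
        assert es.infer_strand(0.04, 0.0, min_expr=0.05) == "no_call"
        assert es.infer_strand(0.5, 0.0, min_expr=0.05) == "sense"


class TestMirnaBinning:
    def test_exact_decreasing_line_gives_r_minus_one(self):
        x = np.linspace(-0.9, 0.9, 30)
        df = pd.DataFrame({"rho_mirna_g": x, "rho_pg_g": -x})
        res = es.mirna_binned_correlation(df)
        assert res.r == pytest.approx(-1.0)

    def test_single_bin_mean_and_sd(self):
        df = pd.DataFrame({"rho_mirna_g": [0.55, 0.58],
                           "rho_pg_g": [0.2, 0.4]})
        res = es.mirna_binned_correlation(df)
        row = res.bins[np.isclose(res.bins["bin_lo"], 0.5)].iloc[0]
        assert row["mean_rho_pg_g"] == pytest.approx(0.3)
        assert row["sd_rho_pg_g"] == pytest.approx(np.std([0.2, 0.4], ddof=1))

    def test_bin_means_match_bruteforce_grouping(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(-1, 1, 300)
        y = rng.uniform(-1, 1, 300)
        df = pd.DataFrame({"rho_mirna_g": x, "rho_pg_g": y})
        res = es.mirna_binned_correlation(df, bin_width=0.1)
        assert res.bins["n"].sum() == 300  # every triple in exactly one bin
        for _, row in res.bins.iterrows():
            lo, hi = row["bin_lo"], row["bin_hi"]
            last = hi == res.bins["bin_hi"].max()
            sel = (x >= lo) & ((x <= hi) if last else (x < hi))
            if sel.sum():
                assert row["mean_rho_pg_g"] == pytest.approx(y[sel].mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            es.mirna_binned_correlation(pd.DataFrame(
                {"rho_mirna_g": [], "rho_pg_g": []}))


class TestKdComparison:
    def test_threshold_excludes_weak_responders(self):
        folds = {"a": 1.2, "b": 1.4, "c": 2.0}
        classes = {k: "parent_targeted" for k in folds}
        dists, _ = es.kd_upregulation_comparison(folds, classes)
        assert list(dists["parent_targeted"]) == [1.4, 2.0]

    def test_identical_distributions_give_p_one(self):
        folds = {"a": 1.4, "b": 2.0, "c": 1.4, "d": 2.0}
        classes = {"a": "x", "b": "x", "c": "y", "d": "y"}
        _, table = es.kd_upregulation_comparison(folds, classes)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_class_reports_undefined_p(self):
        folds = {"a": 1.4, "b": 1.1}
        classes = {"a": "x", "b": "y"}
        _, table = es.kd_upregulation_comparison(folds, classes)
        assert np.isnan(table.loc[0, "p"])

    def test_stochastically_larger_class_has_larger_median(self):
        rng = np.random.default_rng(13)
        folds = {}
        classes = {}
        for i in range(100):
            folds[f"a{i}"] = 1.3 + rng.exponential(1.0)
            classes[f"a{i}"] = "parent_other"
            folds[f"b{i}"] = 1.3 + rng.exponential(0.3)
            classes[f"b{i}"] = "parent_targeted"
        dists, table = es.kd_upregulation_comparison(folds, classes)
        assert np.median(dists["parent_other"]) > np.median(
            dists["parent_targeted"])
        assert table["p"].iloc[0] < 0.01
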