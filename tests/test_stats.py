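import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octsaliency.stats import (
    PHASE1_SCREENING,
    build_report,
    describe,
    friedman_w,
    holm_adjust,
    kendalls_w,
    kruskal_groups,
    phase1_rank,
    rank_concordance,
    report_to_tables,
    validate_ratings,
    wilcoxon_holm,
)
from .oracles import friedman_loop

rng = np.random.default_rng(0)


def ratings_df(scores_by_method, n_sets=2):
    rows = []
    for m, per_rater in scores_by_method.items():
        for r, score in enumerate(per_rater):
            for s in range(n_sets):
                rows.append((f"r{r}", ["retina", "general", "resident"][r % 3],
                             "main", s + 1, "CNV", m, score))
    return pd.DataFrame(rows, columns=["rater_id", "group", "form", "image_set",
                                       "diagnosis", "method", "score"])


class TestDescribe:
    def test_all_favorable(self):
        df = ratings_df({"A": [3, 3, 4, 4]}, n_sets=1)
        row = describe(df).iloc[0]
        assert row["mean"] == 3.5 and row["pct_favorable"] == 100.0 and row["pct_low"] == 0.0

    def test_enumerated_five_scores(self):
        df = ratings_df({"A": [0, 1, 2, 3, 4]}, n_sets=1)
        row = describe(df).iloc[0]
        assert row["median"] == 2 and row["pct_favorable"] == 40.0 and row["pct_low"] == 40.0

    def test_degenerate_iqr(self):
        df = ratings_df({"A": [2, 2, 2]}, n_sets=1)
        row = describe(df).iloc[0]
        assert row["q25"] == row["q75"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe(ratings_df({"A": [1]}).iloc[:0])


class TestRankConcordance:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0]
        out = rank_concordance(x, x)
        assert out["tau_b"] == 1.0 and out["rho"] == 1.0
        rev = rank_concordance(x, x[::-1])
        assert rev["tau_b"] == -1.0 and rev["rho"] == -1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_concordance([1, 1, 1], [1, 2, 3])

    def test_screening_table_concordance(self):
        t = PHASE1_SCREENING()
        out = rank_concordance(t["ophthalmologist"], t["ai_specialist"])
        assert round(out["tau_b"], 3) == 0.576
        assert round(out["rho"], 3) == 0.755


class TestPhase1Rank:
    def test_combined_means_from_screening_table(self):
        ranked = phase1_rank(PHASE1_SCREENING())
        means = dict(zip(zip(ranked["method"], ranked["variant"]),
                         ranked["combined_mean"]))
        assert means[("Grad-CAM++", "Baseline")] == 3.04
        assert means[("TRAST", "vs1")] == 3.32  # 3.315 rounded half-up
        assert means[("CGFM-weighted", "Baseline")] == 3.20
        assert means[("Grad-CAM", "Baseline")] == 2.57

    def test_top_ranking_and_tie_flag(self):
        ranked = phase1_rank(PHASE1_SCREENING())
        assert ranked.iloc[0]["method"] == "TRAST" and ranked.iloc[0]["variant"] == "vs1"
        tied = ranked[ranked["combined_mean"] == 3.04]
        assert set(tied["method"]) == {"Grad-CAM++", "CGFM"}
        assert tied["tied"].all() and tied["in_top_k"].all()

    def test_long_format_requires_both_roles(self):
        long = pd.DataFrame({"method": ["A"], "variant": ["b"],
                             "rater_role": ["ophthalmologist"], "mean_score": [2.0]})
        with pytest.raises(ValueError):
            phase1_rank(long)

    def test_single_method_top1(self):
        df = pd.DataFrame({"method": ["A"], "variant": ["b"],
                           "ophthalmologist": [2.0], "ai_specialist": [3.0]})
        out = phase1_rank(df)
        assert out.iloc[0]["combined_mean"] == 2.5 and out.iloc[0]["in_top_k"]


class TestFriedmanW:
    def test_w_arithmetic_from_reported_statistics(self):
        assert round(kendalls_w(14.34, 21, 3), 2) == 0.34
        assert round(kendalls_w(6.50, 4, 3), 2) == 0.81

    def test_perfect_concordance_gives_w_one(self):
        m = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        res = friedman_w(m)
        assert res.effect_size == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_matrices(self):
        for i in range(2000):
            r = np.random.default_rng(i)
            m = r.integers(0, 5, size=(3, 3)).astype(float)
            assert friedman_w(m).statistic == pytest.approx(friedman_loop(m), abs=1e-9)

    def test_matches_scipy_without_ties(self):
        for i in range(50):
            r = np.random.default_rng(500 + i)
            m = r.standard_normal((8, 4))
            chi2, p = sps.friedmanchisquare(*m.T)
            res = friedman_w(m)
            assert res.statistic == pytest.approx(chi2, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            friedman_w(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_w_in_unit_interval(self):
        for i in range(100):
            r = np.random.default_rng(900 + i)
            res = friedman_w(r.integers(0, 5, size=(5, 3)))
            assert -1e-12 <= res.effect_size <= 1 + 1e-12


class TestWilcoxonHolm:
    def test_holm_hand_example(self):
        assert np.allclose(holm_adjust([0.01, 0.03, 0.04]), [0.03, 0.06, 0.06])

    def test_holm_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        for i in range(20):
            p = np.random.default_rng(i).random(6)
            _, adj, _, _ = multipletests(p, method="holm")
            assert np.allclose(holm_adjust(p), adj)

    def test_holm_monotone_and_at_least_raw(self):
        p = np.random.default_rng(1).random(8)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_identical_columns_give_p_one(self):
        m = np.tile(rng.random(6)[:, None], (1, 3))
        for res in wilcoxon_holm(m):
            assert res.p_value == 1.0
            assert all(v == 1.0 for v in res.adjusted_p.values())

    def test_exact_small_sample_p(self):
        # n=6 strictly positive differences: two-sided exact p = 2/2^6 = 1/32
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        res = wilcoxon_holm(np.column_stack([a, b]))
        assert res[0].p_value == pytest.approx(1 / 32, abs=1e-12)


class TestKruskal:
    def test_identical_distributions(self):
        res = kruskal_groups([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_separated_groups(self):
        # ranks 1..4, R = (3, 7): H = 12/20 * (9/2 + 49/2) - 15 = 2.4
        res = kruskal_groups([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert res.statistic == pytest.approx(2.4, abs=1e-12)
        # permutation check: of C(4,2)=6 assignments, the two extreme splits
        # reach H = 2.4, so the permutation p-value is 2/6
        from itertools import combinations

        vals = np.array([1.0, 2.0, 3.0, 4.0])
        hs = []
        for pick in combinations(range(4), 2):
            g = np.array(["b"] * 4, dtype=object)
            for i in pick:
                g[i] = "a"
            hs.append(kruskal_groups(vals, g).statistic)
        assert (np.array(hs) >= 2.4 - 1e-9).mean() == pytest.approx(2 / 6)

    def test_monotone_transform_invariance(self):
        v = rng.random(9)
        g = np.array(["a", "b", "c"] * 3)
        assert kruskal_groups(v, g).statistic == pytest.approx(
            kruskal_groups(np.exp(5 * v), g).statistic, rel=1e-12
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_groups([1, 2], ["a", "a"])


class TestBuildReport:
    def test_report_structure_main_form(self):
        from octsaliency.synth import RatingSimConfig, synth_ratings

        df = synth_ratings(RatingSimConfig(seed=5))
        rep = build_report(df)
        tables = report_to_tables(rep)
        per_set = tables["per_image_set_main"]
        assert len(per_set) == 10  # one row per image set
        assert {"mean_TRAST", "mean_Grad-CAM++", "mean_CGFM", "p_value"} <= set(per_set.columns)
        pm = rep["forms"]["main"]["participant_matrix"]
        assert pm.shape == (21, 3)
        assert set(rep["by_group"]) == {"TRAST", "Grad-CAM++", "CGFM"}

    def test_duplicate_records_rejected(self):
        df = ratings_df({"A": [1, 2]}, n_sets=1)
        dup = pd.concat([df, df])
        with pytest.raises(ValueError):
            validate_ratings(dup)
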