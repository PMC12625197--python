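"""Confusion metrics, DeLong AUC, logistic fits, rank tests, correlation
summaries, APOE concordance and over-representation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nulisapipe import (
    apoe_concordance,
    confusion_metrics,
    kruskal_dunn,
    logistic_predictor,
    overrepresentation_test,
    platform_correlation,
    roc_auc_delong,
)
from nulisapipe.reference_counts import expand_confusion, matched_platform_table


class TestConfusion:
    def test_direct_arithmetic(self):
        pred, ref = expand_confusion(tp=80, fp=20, tn=90, fn=10)
        c = confusion_metrics(pred, ref)
        assert c.ppv == pytest.approx(0.80)
        assert c.npv == pytest.approx(0.90)
        assert c.concordance == pytest.approx(85.00)

    def test_perfect_agreement(self):
        c = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert c.concordance == 100.00
        assert c.ppv == 1.0 and c.npv == 1.0

    def test_intermediate_labels_excluded(self):
        c = confusion_metrics([1, "intermediate", 0], [1, 1, 0])
        assert c.n == 2 and c.n_excluded == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_identities_hold_on_every_input(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        c = confusion_metrics(*expand_confusion(tp, fp, tn, fn))
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        # ties round away from zero (so 15.625% -> 15.63, not banker's 15.62)
        from fractions import Fraction

        exact = Fraction(10000 * (tp + tn), tp + fp + tn + fn)
        half_away = float((exact + Fraction(1, 2)).__floor__()) / 100
        assert c.concordance == pytest.approx(half_away, abs=1e-9)


class TestDeLongAUC:
    def test_perfect_separation(self):
        r = roc_auc_delong([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.auc == 1.0

    def test_uninformative_scores(self):
        r = roc_auc_delong([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert r.auc == 0.5

    def test_exhaustive_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.normal(size=8), 1)  # force some ties
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        r = roc_auc_delong(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        total = 0.0
        for p, q in itertools.product(pos, neg):
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
        assert r.auc == pytest.approx(total / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_sklearn_on_random_fixtures(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(5):
            scores = rng.normal(size=50)
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            r = roc_auc_delong(scores, labels)
            assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
            assert r.ci_low <= r.auc <= r.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_delong([1, 2, 3], [1, 1, 1])


class TestLogistic:
    def test_intercept_only_recovers_prevalence(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        fit = logistic_predictor(y, pd.DataFrame(index=range(10)))
        assert fit["fitted"] == pytest.approx(np.full(10, 0.3), abs=1e-6)

    def test_independent_predictor_coefficient_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 400)
        x = rng.normal(size=400)
        fit = logistic_predictor(y, pd.DataFrame({"x": x}))
        assert abs(fit["coefficients"]["x"]) < 3 * fit["se"]["x"]

    def test_twelve_row_fixture_matches_grid_oracle(self):
        x = np.array([-2.1, -1.7, -1.2, -0.8, -0.4, -0.1, 0.2, 0.6, 1.0, 1.4, 1.9, 2.3])
        y = np.array([0, 0, 0, 1, 0, 0, 1, 1, 0, 1, 1, 1])
        fit = logistic_predictor(y, pd.DataFrame({"x": x}))

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        # coarse-to-fine grid search
        b0s = np.linspace(-3, 3, 121)
        b1s = np.linspace(-1, 5, 121)
        for _ in range(4):
            grid = np.array([[nll(a, b) for b in b1s] for a in b0s])
            i, j = np.unravel_index(grid.argmin(), grid.shape)
            w0 = (b0s[-1] - b0s[0]) / 10
            w1 = (b1s[-1] - b1s[0]) / 10
            b0s = np.linspace(b0s[i] - w0, b0s[i] + w0, 121)
            b1s = np.linspace(b1s[j] - w1, b1s[j] + w1, 121)
        assert fit["coefficients"]["const"] == pytest.approx(b0s[60], abs=1e-4)
        assert fit["coefficients"]["x"] == pytest.approx(b1s[60], abs=1e-4)

    def test_complete_separation_detected(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(int)
        with pytest.raises(ValueError, match="separation|failed"):
            logistic_predictor(y, pd.DataFrame({"x": x}))


class TestKruskalDunn:
    def test_identical_distributions_h_zero(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        v = np.concatenate([[1.0, 2.0, 3.0]] * 3)
        out = kruskal_dunn(v, g, [("a", "b")])
        assert out["H"] == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equals_rank_sum_test(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=40)
        g = np.repeat(["a", "b"], 20)
        out = kruskal_dunn(v, g, [("a", "b")])
        # chi-square(1) on H is the square of the Dunn/rank-sum z
        assert out["H"] == pytest.approx(out["dunn"].loc[0, "z"] ** 2, abs=1e-10)
        assert out["p"] == pytest.approx(out["dunn"].loc[0, "p_raw"], abs=1e-10)

    def test_three_group_textbook_formula(self):
        v = np.array([2.9, 3.0, 2.5, 2.6, 3.2, 3.8, 2.7, 4.0, 2.4, 2.8, 3.4, 3.7, 2.2, 2.0])
        g = np.array(["x"] * 5 + ["y"] * 4 + ["z"] * 5)
        out = kruskal_dunn(v, g, [("x", "y")])
        ranks = stats.rankdata(v)
        N = len(v)
        h = 12 / (N * (N + 1)) * sum(
            ranks[g == k].sum() ** 2 / (g == k).sum() for k in "xyz"
        ) - 3 * (N + 1)
        assert out["H"] == pytest.approx(h, abs=1e-10)

    def test_bonferroni_is_m_times_p_capped(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=60)
        g = np.repeat(["a", "b", "c"], 20)
        comps = [("a", "b"), ("a", "c")]
        out = kruskal_dunn(v, g, comps)
        for _, row in out["dunn"].iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, 2 * row["p_raw"]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([1.0, 2.0], ["a", "a"], [("a", "b")])


class TestPlatformCorrelation:
    def test_identical_pairs_r_one(self):
        df = pd.DataFrame({"analyte": ["a"] * 5, "x": range(5), "y": range(5)})
        table, _ = platform_correlation(df)
        assert table.loc["a", "r"] == pytest.approx(1.0)

    def test_planted_profile_percentage(self):
        df = matched_platform_table(n_high=86, n_total=123, seed=1)
        _, summary = platform_correlation(df, threshold=0.7)
        assert summary["n_above_threshold"] == 86
        assert summary["pct_above_threshold"] == 69.92

    def test_constant_vector_skipped(self):
        df = pd.DataFrame({"analyte": ["a"] * 4, "x": [1.0] * 4, "y": [1, 2, 3, 4]})
        table, summary = platform_correlation(df)
        assert "a" in summary["skipped"]


class TestApoeConcordance:
    def test_perfect_calls(self):
        calls = [1, 1, 0, 0]
        genos = ["e4/e4", "e3/e4", "e3/e3", "e2/e3"]
        out = apoe_concordance(calls, genos)
        assert out["overall"].concordance == 100.00
        assert all(v["accuracy_pct"] == 100.00 for v in out["per_genotype"].values())

    def test_unknown_genotype_excluded(self):
        out = apoe_concordance([1, 0], ["e4/e4", "e5/e5"])
        assert out["excluded_genotypes"] == ["e5/e5"]
        assert out["overall"].n == 1

    def test_accepts_unicode_epsilon(self):
        out = apoe_concordance([1, 0], ["ε3/ε4", "ε3/ε3"])
        assert out["overall"].concordance == 100.00


class TestOverrepresentation:
    def test_pathway_equals_background_fold_one(self):
        bg = {f"g{i}" for i in range(30)}
        da = {f"g{i}" for i in range(10)}
        table = overrepresentation_test(da, {"all": bg}, bg)
        assert table.loc["all", "fold_enrichment"] == pytest.approx(1.0)

    def test_zero_overlap(self):
        bg = {f"g{i}" for i in range(30)}
        table = overrepresentation_test(
            {"g0", "g1"}, {"pw": {"g20", "g21"}}, bg
        )
        assert table.loc["pw", "fold_enrichment"] == 0.0
        assert table.loc["pw", "p_raw"] == pytest.approx(1.0)

    def test_fixture_matches_combinatorial_enumeration(self):
        from math import comb

        bg = [f"g{i}" for i in range(100)]
        pw = set(bg[:10])  # K = 10
        da = set(bg[:4]) | set(bg[50:66])  # n = 20, k = 4
        table = overrepresentation_test(da, {"pw": pw}, bg)
        assert table.loc["pw", "fold_enrichment"] == pytest.approx(2.0)
        expected_p = sum(
            comb(10, k) * comb(90, 20 - k) for k in range(4, 11)
        ) / comb(100, 20)
        assert table.loc["pw", "p_raw"] == pytest.approx(expected_p, rel=1e-10)

    def test_da_outside_background_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test({"zz"}, {}, {"g1"})


class TestProteoformCaller:
    def test_gmm_based_call_concordant_but_imperfect(self):
        from nulisapipe import (
            CohortConfig,
            call_e4_from_proteoform,
            generate_cohort,
            run_qc,
        )
        from nulisapipe.synthetic import APOE_ANALYTE

        cohort = generate_cohort(CohortConfig(n_per_group=200, n_analytes=12, seed=13))
        filtered, _ = run_qc(cohort.matrix)  # mask spikes before mixture fitting
        vals = filtered.values[APOE_ANALYTE]
        ok = vals.notna()
        calls = call_e4_from_proteoform(vals[ok].to_numpy())
        genos = cohort.annotation.set_index("sample_id").loc[ok[ok].index, "apoe"]
        out = apoe_concordance(calls, genos)
        assert out["overall"].concordance > 85.0
        # genotype-conditional overlap is planted, so perfection is not expected
        assert out["overall"].concordance < 100.0

    def test_threshold_override(self):
        from nulisapipe import call_e4_from_proteoform

        calls = call_e4_from_proteoform([1.0, 2.0, 3.0], threshold=2.5)
        assert calls.tolist() == [0, 0, 1]


class TestGmtRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        from nulisapipe import read_gmt, write_gmt

        amap = {"pwA": {"g1", "g2", "g3"}, "pwB": {"g2", "g9"}}
        path = tmp_path / "sets.gmt"
        write_gmt(amap, path)
        assert read_gmt(path) == amap
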