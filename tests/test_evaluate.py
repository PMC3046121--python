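import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import batchbench as bb
from batchbench.evaluate import _delong_placements

from conftest import make_expr, make_sheet


class TestStandardizeGenes:
    def test_postconditions(self):
        rng = np.random.default_rng(0)
        expr = make_expr(rng.normal(7, 3, (50, 20)))
        out = bb.standardize_genes(expr)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10
        assert np.abs(out.values.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(0, 2, (30, 15)))
        once = bb.standardize_genes(expr)
        twice = bb.standardize_genes(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_within_stratum_standardization(self):
        rng = np.random.default_rng(2)
        expr = make_expr(rng.normal(5, 2, (20, 8)))
        sheet = make_sheet(["B1"] * 8, ["a", "b"] * 4,
                          extra={"replicate_group": ["R1"] * 4 + ["R2"] * 4})
        out = bb.standardize_genes(expr, sheet, within="replicate_group")
        for idx in (slice(0, 4), slice(4, 8)):
            assert np.abs(out.values[:, idx].mean(axis=1)).max() < 1e-10

    def test_probe_effect_experiment(self):
        res = bb.standardization_experiment(seed=0)
        assert res["min_before"] > 0.9
        assert abs(res["median_after"]) < 0.05


class TestReplicateCorrelation:
    def test_identical_and_negated_replicates(self):
        rng = np.random.default_rng(0)
        expr = make_expr(rng.normal(0, 1, (10, 6)))
        np.testing.assert_allclose(bb.replicate_gene_correlation(expr, expr), 1.0)
        neg = expr.with_values(-expr.values)
        np.testing.assert_allclose(bb.replicate_gene_correlation(expr, neg), -1.0)

    def test_hand_computed_single_gene(self):
        a = np.array([[1.0, 2.0, 3.0, 5.0]])
        b = np.array([[2.0, 1.0, 4.0, 6.0]])
        # direct product-moment formula
        ac, bc = a - a.mean(), b - b.mean()
        expected = (ac * bc).sum() / np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
        r = bb.replicate_gene_correlation(make_expr(a), make_expr(b))
        assert r[0] == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        expr = make_expr(np.ones((2, 2)) + np.arange(2)[:, None])
        with pytest.raises(ValueError, match="3 paired"):
            bb.replicate_gene_correlation(expr, expr)


def _icc_sheet(n_subj, k):
    ids = [f"{s}.{r}" for r in range(k) for s in range(n_subj)]
    return bb.SampleSheet(
        __import__("pandas").DataFrame(
            {"batch": ["B1"] * (n_subj * k),
             "group": ["all"] * (n_subj * k),
             "replicate_group": [f"R{r}" for r in range(k) for _ in range(n_subj)],
             "subject": [f"P{s}" for _ in range(k) for s in range(n_subj)]},
            index=__import__("pandas").Index(ids, name="sample_id")))


class TestIcc:
    def test_identical_replicates_give_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(7, 1, (5, 4))
        expr = make_expr(np.hstack([base, base, base]),
                         ids=[f"{s}.{r}" for r in range(3) for s in range(4)])
        icc = bb.icc_per_gene(expr, _icc_sheet(4, 3))
        np.testing.assert_allclose(icc, 1.0, atol=1e-9)

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(0, 1, (200, 30)),
                         ids=[f"{s}.{r}" for r in range(3) for s in range(10)])
        icc = bb.icc_per_gene(expr, _icc_sheet(10, 3))
        assert abs(np.median(icc)) < 0.2  # small, possibly negative (documented)

    def test_matches_anova_sums_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        n_subj, k = 6, 3
        y = rng.normal(0, 1, (4, n_subj * k)) + \
            np.tile(rng.normal(0, 2, n_subj), k)
        expr = make_expr(y, ids=[f"{s}.{r}" for r in range(k) for s in range(n_subj)])
        icc = bb.icc_per_gene(expr, _icc_sheet(n_subj, k))
        for gi in range(4):
            table = y[gi].reshape(k, n_subj).T           # subjects x replicates
            grand = table.mean()
            ssb = k * ((table.mean(axis=1) - grand) ** 2).sum()
            ssw = ((table - table.mean(axis=1, keepdims=True)) ** 2).sum()
            msb = ssb / (n_subj - 1)
            msw = ssw / (n_subj * (k - 1))
            expected = (msb - msw) / (msb + (k - 1) * msw)
            assert icc[gi] == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc1(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        n_subj, k = 8, 3
        y = (np.tile(rng.normal(0, 1.5, n_subj), k)
             + rng.normal(0, 1, n_subj * k))[None, :]
        ids = [f"{s}.{r}" for r in range(k) for s in range(n_subj)]
        expr = make_expr(np.vstack([y, y + 1]), ids=ids)
        icc = bb.icc_per_gene(expr, _icc_sheet(n_subj, k))
        long = pd.DataFrame({
            "subject": [f"P{s}" for _ in range(k) for s in range(n_subj)],
            "rater": [f"R{r}" for r in range(k) for _ in range(n_subj)],
            "score": y.ravel()})
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        icc1 = ref.loc[ref.Type == "ICC(1,1)", "ICC"].iloc[0]
        assert icc[0] == pytest.approx(icc1, abs=1e-9)

    def test_incomplete_design_rejected(self):
        sheet = _icc_sheet(4, 3)
        data = sheet.data.drop(index=["0.2"])
        import pandas as pd
        broken = bb.SampleSheet(data)
        expr = make_expr(np.random.default_rng(0).normal(0, 1, (2, 11)),
                         ids=list(data.index))
        with pytest.raises(ValueError, match="incomplete"):
            bb.icc_per_gene(expr, broken)


class TestFisherZ:
    def test_known_values(self):
        assert bb.fisher_z(0.0) == 0.0
        assert bb.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    @given(st.floats(-0.999, 0.999))
    def test_odd_symmetry(self, r):
        assert bb.fisher_z(-r) == pytest.approx(-bb.fisher_z(r), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bb.fisher_z(1.5)


class TestPairedZShift:
    def test_no_change_gives_p_one(self):
        z = np.arange(10.0)
        median, p = bb.paired_z_shift_test(z, z)
        assert median == 0.0 and p == 1.0

    def test_forced_shift_detected(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1, 1000)
        median, p = bb.paired_z_shift_test(z, z + 1)
        assert median == pytest.approx(1.0)
        assert p < 1e-4

    def test_matches_exact_enumeration_on_ten_pairs(self):
        rng = np.random.default_rng(5)
        before = rng.normal(0, 1, 10)
        after = before + rng.normal(0.3, 0.8, 10)
        _, p = bb.paired_z_shift_test(before, after)
        # brute force: distribution of the signed-rank statistic over all
        # 2^10 sign assignments of the |differences| ranks
        d = after - before
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        stats_all = [sum(r for r, s in zip(ranks, signs) if s)
                     for signs in itertools.product([0, 1], repeat=10)]
        stats_all = np.array(stats_all)
        w_min = min(w_obs, total - w_obs)
        p_exact = np.mean(np.minimum(stats_all, total - stats_all) <= w_min)
        assert p == pytest.approx(p_exact, abs=1e-10)


class TestFoldChangeMetrics:
    def test_identical_groups_give_zero_fc(self):
        expr = make_expr(np.tile([[1.0, 2.0, 1.0, 2.0]], (3, 1)))
        sheet = make_sheet(["B1"] * 4, ["a", "a", "b", "b"])
        fc = bb.observed_log2_fc(expr, sheet)
        np.testing.assert_allclose(fc, 0.0)

    def test_hand_computed_difference(self):
        expr = make_expr([[1.0, 3.0, 4.0, 8.0]])
        sheet = make_sheet(["B1"] * 4, ["a", "a", "b", "b"])
        assert bb.observed_log2_fc(expr, sheet)[0] == pytest.approx(4.0)

    def test_group_order_follows_level_ordering(self):
        import pandas as pd
        expr = make_expr([[1.0, 3.0, 4.0, 8.0]])
        sheet = bb.SampleSheet(pd.DataFrame(
            {"batch": ["B1"] * 4,
             "group": pd.Categorical(["b", "b", "a", "a"],
                                     categories=["a", "b"])},
            index=pd.Index([f"S{i + 1:03d}" for i in range(4)],
                           name="sample_id")))
        # second level is "b": mean(b) - mean(a) = 2 - 6
        assert bb.observed_log2_fc(expr, sheet)[0] == pytest.approx(-4.0)

    def test_agreement_identity_and_attenuation(self):
        nominal = np.concatenate([np.tile(bb.FOLD_CHANGE_LEVELS, 10),
                                  np.zeros(50)])
        de = nominal != 0
        r2, slope = bb.fc_agreement(nominal, nominal, de)
        assert (r2, slope) == (pytest.approx(1.0), pytest.approx(1.0))
        r2, slope = bb.fc_agreement(nominal, 0.9 * nominal, de)
        assert slope == pytest.approx(0.9)
        assert r2 == pytest.approx(1.0)

    def test_slope_homogeneity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 100)
        y1 = 1.0 * x + rng.normal(0, 0.05, 100)
        y2 = 0.5 * x + rng.normal(0, 0.05, 100)
        assert bb.slope_homogeneity_test(x, y1, x, y1) == pytest.approx(1.0)
        assert bb.slope_homogeneity_test(x, y1, x, y2) < 1e-4

    def test_slope_homogeneity_matches_manual_ancova(self):
        x1 = np.array([0.0, 1.0, 2.0, 3.0])
        y1 = np.array([0.1, 1.2, 1.9, 3.2])
        x2 = np.array([0.0, 1.0, 2.0, 3.0])
        y2 = np.array([0.0, 0.4, 1.1, 1.4])
        p = bb.slope_homogeneity_test(x1, y1, x2, y2)
        # manual ANCOVA: fit both separate slopes, compare to common slope
        b1 = np.polyfit(x1, y1, 1)[0]
        b2 = np.polyfit(x2, y2, 1)[0]
        sxx = ((x1 - x1.mean()) ** 2).sum()
        rss_sep = (((y1 - y1.mean()) - b1 * (x1 - x1.mean())) ** 2).sum() + \
                  (((y2 - y2.mean()) - b2 * (x2 - x2.mean())) ** 2).sum()
        bc = (b1 * sxx + b2 * sxx) / (2 * sxx)
        rss_com = (((y1 - y1.mean()) - bc * (x1 - x1.mean())) ** 2).sum() + \
                  (((y2 - y2.mean()) - bc * (x2 - x2.mean())) ** 2).sum()
        f = (rss_com - rss_sep) / (rss_sep / 4)          # df = 8 - 4
        p_manual = stats.f.sf(f, 1, 4)
        assert p == pytest.approx(p_manual, abs=1e-10)


class TestDeTesting:
    def test_identical_groups_give_p_one(self):
        expr = make_expr([[1.0, 1.0, 1.0, 1.0]])
        sheet = make_sheet(["B1"] * 4, ["a", "a", "b", "b"])
        assert bb.de_pvalues(expr, sheet)[0] == 1.0

    def test_huge_effect_tiny_p(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(5, 0.01, 10)])
        expr = make_expr(vals[None, :])
        sheet = make_sheet(["B1"] * 20, ["a"] * 10 + ["b"] * 10)
        assert bb.de_pvalues(expr, sheet)[0] < 1e-10

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(1)
        g, per = 10_000, 10
        expr = make_expr(rng.normal(0, 1, (g, 2 * per)))
        sheet = make_sheet(["B1"] * (2 * per), ["a"] * per + ["b"] * per)
        p = bb.de_pvalues(expr, sheet)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / g)
        assert abs(rate - 0.05) < 4 * se


def _auc_bruteforce(scores, truth):
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([5.0, 4.0, 3.0, 1.0, 0.5])
        truth = np.array([True, True, True, False, False])
        assert bb.roc_auc(scores, truth).auc == 1.0

    def test_toy_counts_pairs(self):
        scores = np.array([3.0, 1.0, 2.0, 2.0, 0.0])
        truth = np.array([True, True, False, False, False])
        assert bb.roc_auc(scores, truth).auc == pytest.approx(
            _auc_bruteforce(scores, truth))

    @given(st.integers(0, 2 ** 32 - 1))
    def test_trapezoid_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(0, 1, n), 1)   # ties likely
        truth = rng.random(n) < 0.4
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        assert bb.roc_auc(scores, truth).auc == pytest.approx(
            _auc_bruteforce(scores, truth), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            bb.roc_auc(np.arange(4.0), np.ones(4, dtype=bool))


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 100)
        truth = rng.random(100) < 0.3
        assert bb.auc_difference_test(scores, scores, truth) == 1.0

    def test_perfect_vs_random_highly_significant(self):
        rng = np.random.default_rng(1)
        truth = np.concatenate([np.ones(500, bool), np.zeros(500, bool)])
        perfect = np.concatenate([np.ones(500), np.zeros(500)])
        noise = rng.normal(0, 1, 1000)
        assert bb.auc_difference_test(perfect, noise, truth) < 1e-6

    def test_placements_match_structural_components(self):
        scores = np.array([0.9, 0.8, 0.35, 0.7, 0.2, 0.1])
        truth = np.array([True, True, True, False, False, False])
        auc, v_pos, v_neg = _delong_placements(scores, truth)
        pos, neg = scores[truth], scores[~truth]
        v_pos_manual = [np.mean([(p > n) + 0.5 * (p == n) for n in neg])
                        for p in pos]
        v_neg_manual = [np.mean([(p > n) + 0.5 * (p == n) for p in pos])
                        for n in neg]
        np.testing.assert_allclose(v_pos, v_pos_manual)
        np.testing.assert_allclose(v_neg, v_neg_manual)
        assert auc == pytest.approx(_auc_bruteforce(scores, truth))


class TestMcc:
    def test_extremes(self):
        assert bb.mcc_from_counts(100, 0, 100, 0) == 1.0
        assert bb.mcc_from_counts(0, 100, 0, 100) == -1.0
        assert bb.mcc_from_counts(0, 0, 10, 5) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            bb.mcc_from_counts(-1, 0, 0, 1)

    def test_confounded_style_counts_match_binary_vector_oracle(self):
        # counts reconstructed from a 10,000-gene confusion summary
        tp, fp, tn, fn = 1023, 5495, 3305, 177
        predicted = np.concatenate([np.ones(tp + fp), np.zeros(tn + fn)])
        actual = np.concatenate([np.ones(tp), np.zeros(fp),
                                 np.zeros(tn), np.ones(fn)])
        oracle = stats.pearsonr(predicted, actual).statistic
        assert bb.mcc_from_counts(tp, fp, tn, fn) == pytest.approx(oracle, abs=1e-12)

    @given(st.tuples(st.integers(0, 200), st.integers(0, 200),
                     st.integers(0, 200), st.integers(0, 200)))
    def test_matches_sklearn(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        from sklearn.metrics import matthews_corrcoef
        predicted = np.concatenate([np.ones(tp + fp), np.zeros(tn + fn)])
        actual = np.concatenate([np.ones(tp), np.zeros(fp),
                                 np.zeros(tn), np.ones(fn)])
        assert bb.mcc_from_counts(tp, fp, tn, fn) == pytest.approx(
            matthews_corrcoef(actual, predicted), abs=1e-9)
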