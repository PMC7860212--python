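"""Evaluation battery: every statistic is checked against a worked example
or a brute-force oracle (all-pairs concordance for AUROC, placement values
for DeLong, exhaustive threshold enumeration for AUPRC, direct counting for
NRI, lifelines for the Cox fit on tie-free data)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyfrax import evaluate as ev


# ---------------------------------------------------------------------------
# stratification and incidence


class TestPercentileStratify:
    def test_nine_groups_with_canonical_sizes(self):
        z = np.random.default_rng(0).normal(size=1000)
        g = ev.percentile_stratify(z)
        assert len(np.unique(g)) == 9
        np.testing.assert_array_equal(
            np.bincount(g), [10, 40, 150, 200, 200, 200, 150, 40, 10]
        )

    def test_all_tied_scores_collapse_to_one_group(self):
        g = ev.percentile_stratify(np.zeros(100))
        assert len(np.unique(g)) == 1

    def test_non_ascending_edges_rejected(self):
        with pytest.raises(ValueError):
            ev.percentile_stratify(np.arange(10.0), edges=(0.5, 0.2))


class TestIncidenceByGroup:
    def test_wilson_closed_form(self):
        groups = np.zeros(50, dtype=int)
        events = np.r_[np.ones(3), np.zeros(47)]
        row = ev.incidence_by_group(groups, events).iloc[0]
        assert row["proportion"] == pytest.approx(0.06)
        # Wilson interval closed form
        p_hat, n, z = 0.06, 50, stats.norm.ppf(0.975)
        center = (p_hat + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert row["ci_low"] == pytest.approx(center - half, abs=1e-10)
        assert row["ci_high"] == pytest.approx(center + half, abs=1e-10)
        assert 0 < row["ci_low"] and row["ci_high"] < 0.17

    def test_boundary_counts(self):
        zero = ev.incidence_by_group(np.zeros(100, int), np.zeros(100)).iloc[0]
        assert zero["ci_low"] == 0.0
        full = ev.incidence_by_group(np.zeros(100, int), np.ones(100)).iloc[0]
        assert full["ci_high"] == 1.0

    def test_clopper_pearson_option(self):
        row = ev.incidence_by_group(
            np.zeros(50, int), np.r_[np.ones(3), np.zeros(47)], ci_method="clopper_pearson"
        ).iloc[0]
        lo, hi = stats.beta.ppf(0.025, 3, 48), stats.beta.ppf(0.975, 4, 47)
        assert row["ci_low"] == pytest.approx(lo, abs=1e-10)
        assert row["ci_high"] == pytest.approx(hi, abs=1e-10)


# ---------------------------------------------------------------------------
# logistic association


class TestLogisticFit:
    def test_two_by_two_table_odds_ratio(self):
        # a=20, b=80, c=10, d=90 -> OR = (20*90)/(80*10) = 2.25
        y = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
        x = np.r_[np.ones(100), np.zeros(100)]
        fit = ev.logistic_fit(x[:, None], y)
        assert fit.odds_ratios[1] == pytest.approx(2.25, rel=1e-6)

    def test_intercept_only_recovers_mean(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = ev.logistic_fit(np.empty((100, 0)), y)
        from scipy.special import expit

        assert expit(fit.params[0]) == pytest.approx(0.3, rel=1e-8)

    def test_null_covariate_ci_coverage(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.standard_normal(5000)
            y = rng.binomial(1, 0.1, size=5000)
            fit = ev.logistic_fit(x[:, None], y)
            if fit.or_ci_low[1] <= 1.0 <= fit.or_ci_high[1]:
                hits += 1
        assert hits / reps >= 0.93

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = ev.logistic_fit(x[:, None], y)
        assert fit.separation_flag

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            ev.logistic_fit(np.zeros((10, 1)), np.ones(10))


class TestLikelihoodRatioTest:
    def test_identical_loglik_gives_p_one(self):
        assert ev.likelihood_ratio_test(-10.0, -10.0, 1) == 1.0

    def test_chi2_quantile_identity(self):
        assert ev.likelihood_ratio_test(0.0, 3.841 / 2, 1) == pytest.approx(0.05, abs=1e-4)

    def test_chi2_tail(self):
        assert ev.likelihood_ratio_test(0.0, 5.0, 1) == pytest.approx(1.565e-3, rel=1e-3)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            ev.likelihood_ratio_test(-5.0, -6.0, 1)


class TestPrevalenceMatchBinarize:
    def test_exact_floor_counts(self):
        z = np.random.default_rng(2).normal(size=100)
        ind = ev.prevalence_match_binarize(z, 0.25)
        assert ind.sum() == 25
        assert set(np.flatnonzero(ind)) == set(np.argsort(z)[:25])

    def test_floor_arithmetic(self):
        z = np.random.default_rng(3).normal(size=1000)
        assert ev.prevalence_match_binarize(z, 0.242).sum() == 242

    def test_order_invariance_by_id(self):
        z = np.random.default_rng(4).normal(size=50)
        ind = ev.prevalence_match_binarize(z, 0.3)
        rev = ev.prevalence_match_binarize(z[::-1], 0.3)[::-1]
        np.testing.assert_array_equal(ind, rev)


# ---------------------------------------------------------------------------
# discrimination


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += (a > b) + 0.5 * (a == b)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        assert ev.roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1])) == 0.75

    def test_perfect_separation(self):
        s = np.random.default_rng(5).normal(size=100)
        y = (s > np.median(s)).astype(int)
        assert ev.roc_auc(s, y) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=2000)
        y = rng.binomial(1, 0.3, size=2000)
        assert ev.roc_auc(s, y) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 200)
        s = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        y = rng.binomial(1, 0.4, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert ev.roc_auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc(np.arange(5.0), np.ones(5))

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=400)
        y = (s + rng.normal(size=400) > 0).astype(int)
        auc = ev.roc_auc(s, y)
        lo, hi = ev.bootstrap_ci(ev.roc_auc, s, y, B=200, seed=8)
        assert lo <= auc <= hi


class TestDelong:
    def test_identical_scores_give_p_one(self):
        s = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        diff, var, p = ev.delong_test(s, s, y)
        assert diff == 0.0 and p == 1.0

    def test_rank_invariance(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=60)
        y = rng.binomial(1, 0.5, size=60)
        diff, _, _ = ev.delong_test(2 * s + 5, s, y)
        assert diff == pytest.approx(0.0, abs=1e-12)

    def test_variance_matches_brute_force_placement_oracle(self):
        rng = np.random.default_rng(10)
        n = 20
        sa = rng.normal(size=n)
        sb = 0.5 * sa + rng.normal(size=n)
        y = np.r_[np.ones(8), np.zeros(12)].astype(int)

        def placements(s):
            pos, neg = s[y == 1], s[y == 0]
            v10 = np.empty(len(pos))
            for i, x in enumerate(pos):
                acc = 0.0
                for b in neg:
                    acc += 1.0 if x > b else (0.5 if x == b else 0.0)
                v10[i] = acc / len(neg)
            v01 = np.empty(len(neg))
            for j, b in enumerate(neg):
                acc = 0.0
                for x in pos:
                    acc += 1.0 if x > b else (0.5 if x == b else 0.0)
                v01[j] = acc / len(pos)
            return v10, v01

        v10a, v01a = placements(sa)
        v10b, v01b = placements(sb)
        expected_var = (v10a - v10b).var(ddof=1) / 8 + (v01a - v01b).var(ddof=1) / 12
        _, var, _ = ev.delong_test(sa, sb, y)
        assert var == pytest.approx(expected_var, abs=1e-10)


class TestPrAuc:
    def test_perfect_ranking(self):
        assert ev.pr_auc(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_tied_equals_prevalence(self):
        y = np.r_[np.ones(3), np.zeros(7)].astype(int)
        assert ev.pr_auc(np.zeros(10), y) == pytest.approx(0.3)

    def test_worked_example(self):
        got = ev.pr_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert got == pytest.approx(1 / 2 * 1.0 + 1 / 2 * (2 / 3), abs=1e-12)

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(11)
        s = rng.normal(size=300)
        y = rng.binomial(1, 0.2, size=300)
        assert ev.pr_auc(s, y) == pytest.approx(average_precision_score(y, s), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            ev.pr_auc(np.arange(4.0), np.zeros(4))


# ---------------------------------------------------------------------------
# survival


class TestKaplanMeier:
    def test_product_limit_arithmetic(self):
        km = ev.km_estimator(np.zeros(3), np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]))
        assert km(1) == pytest.approx(2 / 3)
        assert km(2) == pytest.approx(1 / 3)
        assert km(3) == pytest.approx(1 / 3)

    def test_no_events_means_flat_survival(self):
        km = ev.km_estimator(np.zeros(5), np.arange(1.0, 6.0), np.zeros(5))
        assert np.allclose(km(np.arange(1.0, 6.0)), 1.0)

    def test_all_events_reduce_to_ecdf_complement(self):
        exits = np.array([1.0, 2.0, 3.0, 4.0])
        km = ev.km_estimator(np.zeros(4), exits, np.ones(4))
        np.testing.assert_allclose(km(exits), [0.75, 0.5, 0.25, 0.0])

    def test_censoring_age_cap(self):
        km = ev.km_estimator(
            np.array([60.0, 60.0]), np.array([95.0, 85.0]), np.array([1, 1]), censor_age=90
        )
        # the event at 95 is censored at 90: only one death remains
        assert km(89.9) == pytest.approx(0.5)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            ev.km_estimator(np.array([5.0]), np.array([4.0]), np.array([1]))


class TestCox:
    def test_single_concordant_pair(self):
        fit = ev.cox_fit(
            np.zeros(2), np.array([1.0, 2.0]), np.array([1, 1]), np.array([[2.0], [1.0]])
        )
        assert fit.c_index == 1.0

    def test_matches_lifelines_on_tie_free_data(self):
        # Breslow and Efron coincide with no tied event times, so lifelines'
        # start-stop Cox fit is a valid independent oracle here
        from lifelines import CoxTimeVaryingFitter

        rng = np.random.default_rng(12)
        n = 300
        x = rng.standard_normal(n)
        entry = rng.uniform(50, 60, size=n)
        t = rng.exponential(scale=np.exp(-0.5 * x) * 20)
        event = (t < 15).astype(int)
        exit_ = entry + np.minimum(t, 15) + rng.uniform(0, 1e-6, n)  # break ties
        fit = ev.cox_fit(entry, exit_, event, x[:, None])
        df = pd.DataFrame({"start": entry, "stop": exit_, "event": event, "x": x})
        ctv = CoxTimeVaryingFitter(penalizer=0.0)
        ctv.fit(df, start_col="start", stop_col="stop", event_col="event")
        assert fit.params[0] == pytest.approx(ctv.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(ctv.standard_errors_["x"], abs=1e-5)

    def test_null_covariate_coverage(self):
        rng = np.random.default_rng(13)
        hits, reps = 0, 200
        for _ in range(reps):
            n = 2000
            x = rng.standard_normal(n)
            t = rng.exponential(scale=10, size=n)
            event = (t < 5).astype(int)
            exit_ = np.minimum(t, 5) + 1e-9 * rng.random(n)
            fit = ev.cox_fit(np.zeros(n), exit_, event, x[:, None])
            if abs(fit.params[0]) < 3 * fit.se[0]:
                hits += 1
        assert hits / reps >= 0.93

    def test_hazard_ratio_recovery(self):
        rng = np.random.default_rng(14)
        n = 5000
        x = rng.standard_normal(n)
        t = rng.exponential(scale=np.exp(-np.log(2) * x) * 10)
        event = (t < 8).astype(int)
        exit_ = np.minimum(t, 8)
        fit = ev.cox_fit(np.zeros(n), exit_, event, x[:, None])
        assert 1.7 <= fit.hazard_ratios[0] <= 2.35

    def test_c_index_equals_pairwise_concordance_without_censoring(self):
        rng = np.random.default_rng(15)
        n = 80
        risk = rng.normal(size=n)
        exits = rng.permutation(np.arange(1.0, n + 1.0))  # distinct times
        c = ev.harrell_c(risk, np.zeros(n), exits, np.ones(n, int))
        conc = usable = 0.0
        for i in range(n):
            for j in range(n):
                if exits[i] < exits[j]:
                    usable += 1
                    conc += (risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j])
        assert c == pytest.approx(conc / usable, abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            ev.cox_fit(np.zeros(3), np.arange(1.0, 4.0), np.zeros(3), np.ones((3, 1)))


# ---------------------------------------------------------------------------
# reclassification


class TestNri:
    def test_worked_categorical_example(self):
        # events: one moves up across 0.20, none down; nonevents: one moves
        # down, none up -> (1/2 - 0) + (1/2 - 0) = 1.0
        p_old = np.array([0.15, 0.25, 0.25, 0.10])
        p_new = np.array([0.25, 0.25, 0.15, 0.10])
        y = np.array([1, 1, 0, 0])
        res = ev.nri(p_old, p_new, y, cutoffs=0.20)
        assert res["categorical_nri"].estimate == pytest.approx(1.0)

    def test_identical_probabilities_give_zero(self):
        p = np.array([0.1, 0.3, 0.2, 0.05])
        y = np.array([1, 1, 0, 0])
        res = ev.nri(p, p.copy(), y, cutoffs=0.2)
        assert res["categorical_nri"].estimate == 0.0
        assert res["continuous_nri"].estimate == 0.0

    def test_matches_direct_counting_oracle(self):
        rng = np.random.default_rng(16)
        p_old = rng.uniform(0.01, 0.5, size=10)
        p_new = np.clip(p_old + rng.normal(0, 0.1, size=10), 0.01, 0.6)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        cutoff = 0.2
        res = ev.nri(p_old, p_new, y, cutoffs=cutoff)

        def count(mask_fun):
            up_e = down_e = up_ne = down_ne = 0
            for po, pn, yi in zip(p_old, p_new, y):
                up, down = mask_fun(po, pn)
                if yi:
                    up_e += up
                    down_e += down
                else:
                    up_ne += up
                    down_ne += down
            n_e, n_ne = int(y.sum()), int((1 - y).sum())
            return (up_e - down_e) / n_e + (down_ne - up_ne) / n_ne

        cat = count(lambda po, pn: ((po < cutoff <= pn), (pn < cutoff <= po)))
        cont = count(lambda po, pn: ((pn > po), (pn < po)))
        assert res["categorical_nri"].estimate == pytest.approx(cat, abs=1e-12)
        assert res["continuous_nri"].estimate == pytest.approx(cont, abs=1e-12)

    def test_bootstrap_ci_method(self):
        rng = np.random.default_rng(17)
        p_old = rng.uniform(0.05, 0.4, 200)
        p_new = np.clip(p_old + rng.normal(0, 0.05, 200), 0.01, 0.8)
        y = rng.binomial(1, 0.3, 200)
        res = ev.nri(p_old, p_new, y, cutoffs=0.2, ci_method="bootstrap", B=100, seed=18)
        r = res["categorical_nri"]
        assert r.ci_low <= r.ci_high
        assert r.method == "bootstrap:100"

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            ev.nri(np.array([0.1, 0.2]), np.array([0.2, 0.3]), np.array([1, 1]))


class TestIdi:
    def test_worked_example(self):
        # events: mean improvement 0.1; nonevents: mean change -0.1
        res = ev.idi(
            np.array([0.2, 0.4, 0.2]), np.array([0.3, 0.5, 0.1]), np.array([1, 1, 0])
        )
        assert res.estimate == pytest.approx(0.2, abs=1e-12)

    def test_identical_probabilities_give_zero(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([1, 0, 1, 0])
        assert ev.idi(p, p.copy(), y).estimate == 0.0

    def test_label_swap_negates(self):
        rng = np.random.default_rng(19)
        p_old = rng.uniform(0, 1, 30)
        p_new = rng.uniform(0, 1, 30)
        y = rng.binomial(1, 0.5, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        a = ev.idi(p_old, p_new, y).estimate
        b = ev.idi(p_old, p_new, 1 - y).estimate
        assert a == pytest.approx(-b, abs=1e-12)
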